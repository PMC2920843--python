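"""Conformational and solvent entropy estimators.

Two distinct entropies appear in the binding free energy:

* the ligand's conformational (vibrational) entropy, estimated
  quasiharmonically from the mass-weighted covariance of heavy-atom
  fluctuations after projecting out rigid-body motion (evaluated at 298 K);
* the excess entropy of interfacial water relative to bulk, from the
  first-order term of the inhomogeneous-fluid-solvation-theory expansion of
  spatial and orientational correlation functions (evaluated at 300 K),
  estimated with nearest-neighbour estimators and reported as −TΔS so that
  localized (ordered) sites give positive, unfavourable values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .mm import KB
from .model_io import ParameterizedSystem, Trajectory

# unit conversions for quasiharmonic frequencies
_KCALMOL_PER_AMU_A2_TO_S2 = 4.184e26  # 1 kcal/(mol amu Å²) in s⁻²
_C_CM_S = 2.99792458e10
_HBAR_J_S = 1.0545718176e-34
_KB_J_K = 1.380649e-23

# C2 rotation of the water molecule about its symmetry axis, as a unit
# quaternion (rotation by pi about the template z axis).
WATER_C2_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass
class QuasiharmonicResult:
    """Vibrational modes and entropy of a fluctuating selection."""

    frequencies_cm1: np.ndarray
    TS: float  # kcal/mol at `temperature`
    temperature: float
    n_modes: int
    eigenvalues: np.ndarray = field(repr=False, default=None)


@dataclass
class SiteEntropy:
    """First-order excess entropy of a hydration site, as −TΔS (kcal/mol)."""

    translational: float
    orientational: float
    temperature: float = 300.0

    @property
    def total(self) -> float:
        return self.translational + self.orientational


# ---------------------------------------------------------------------------
# Quasiharmonic conformational entropy
# ---------------------------------------------------------------------------


def _kabsch_weighted(mobile: np.ndarray, ref: np.ndarray,
                     weights: np.ndarray) -> np.ndarray:
    """Weighted least-squares superposition of ``mobile`` onto ``ref``."""
    w = weights[:, None]
    mc = (mobile * w).sum(0) / weights.sum()
    rc = (ref * w).sum(0) / weights.sum()
    a = mobile - mc
    b = ref - rc
    h = (a * w).T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ a.T).T + rc


def harmonic_oscillator_entropy(x: np.ndarray) -> np.ndarray:
    """Quantum harmonic-oscillator entropy per mode in units of k_B.

    ``x = hbar*omega / (k_B T)``; vanishes as x → ∞ and diverges
    logarithmically as x → 0.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        ex = np.exp(-x)
    return x * ex / (1.0 - ex) - np.log1p(-ex)


def quasiharmonic_entropy(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    selection: np.ndarray,
    temperature: float = 298.0,
    n_superpose_iter: int = 5,
) -> QuasiharmonicResult:
    """Quasiharmonic vibrational entropy of the selected (heavy) atoms.

    Frames are superposed onto the iteratively refined average structure by
    mass-weighted rigid-body fit, which projects out translation and
    rotation.  The mass-weighted covariance of the remaining fluctuations
    is diagonalized; each eigenvalue λ (amu Å²) maps to a mode frequency
    ω = sqrt(k_B T / λ), and the 6 smallest-eigenvalue modes (the rigid-body
    null space) are discarded by rank.  TS is the quantum
    harmonic-oscillator entropy summed over the retained modes.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise ValueError("need at least 3 atoms for a quasiharmonic analysis")
    masses = system.masses()[sel]
    if np.any(masses <= 0):
        raise ValueError("all selected atoms need positive masses")
    n_frames = trajectory.n_frames
    n_dof = 3 * sel.size
    if n_frames < n_dof:
        warnings.warn(
            f"{n_frames} frames for {n_dof} degrees of freedom; "
            "covariance will be noisy (3N frames recommended)")
    frames = trajectory.coordinates[:, sel].copy()
    ref = frames.mean(axis=0)
    for _ in range(n_superpose_iter):
        for f in range(n_frames):
            frames[f] = _kabsch_weighted(frames[f], ref, masses)
        new_ref = frames.mean(axis=0)
        if np.max(np.abs(new_ref - ref)) < 1e-10:
            ref = new_ref
            break
        ref = new_ref

    delta = (frames - ref).reshape(n_frames, n_dof)
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    mw = delta * sqrt_m
    cov = mw.T @ mw / n_frames
    evals = np.linalg.eigvalsh(cov)  # ascending
    internal = evals[6:][::-1]  # drop 6 rigid-body null modes by rank
    n_null_extra = int(np.sum(internal < 1e-10))
    if n_null_extra:
        warnings.warn(
            f"covariance rank-deficient beyond the 6 rigid-body modes: "
            f"{n_null_extra} additional near-zero modes")
    kt = KB * temperature
    lam = np.clip(internal, 1e-300, None)
    omega = np.sqrt(kt / lam * _KCALMOL_PER_AMU_A2_TO_S2)  # s^-1
    freq_cm1 = omega / (2.0 * math.pi * _C_CM_S)
    x = _HBAR_J_S * omega / (_KB_J_K * temperature)
    ts = float(temperature * KB * harmonic_oscillator_entropy(x).sum())
    return QuasiharmonicResult(frequencies_cm1=freq_cm1, TS=ts,
                               temperature=temperature,
                               n_modes=internal.size, eigenvalues=internal)


def frequencies_from_covariance(
    covariance: np.ndarray, masses: np.ndarray, temperature: float = 298.0
) -> np.ndarray:
    """Mode frequencies (cm⁻¹) implied by a generating positional covariance.

    Closed-form oracle counterpart to :func:`quasiharmonic_entropy`: the
    covariance is mass-weighted and diagonalized directly, with no
    rigid-body projection and no sampling.
    """
    sqrt_m = np.sqrt(np.repeat(np.asarray(masses, dtype=float), 3))
    mw_cov = covariance * np.outer(sqrt_m, sqrt_m)
    evals = np.linalg.eigvalsh(mw_cov)[::-1]
    evals = evals[evals > 1e-12]
    omega = np.sqrt(KB * temperature / evals * _KCALMOL_PER_AMU_A2_TO_S2)
    return omega / (2.0 * math.pi * _C_CM_S)


# ---------------------------------------------------------------------------
# First-order IFST site entropies (nearest-neighbour estimators)
# ---------------------------------------------------------------------------


def site_translational_entropy(
    oxygen_positions: np.ndarray,
    bulk_density: float,
    temperature: float = 300.0,
    k: int = 1,
) -> float:
    """−TΔS_trans (kcal/mol) of a hydration site from oxygen samples.

    Estimates S_tr = −k_B⟨ln(ρ_site/ρ_bulk)⟩ with ρ_site the probability
    density of the occupying-water oxygen position, via the
    Kozachenko-Leonenko k-nearest-neighbour entropy estimator.  Positive for
    localized sites, ≈0 when the local density matches bulk.
    """
    x = np.asarray(oxygen_positions, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("oxygen_positions must be (n, 3)")
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    if n < 50:
        warnings.warn(f"only {n} samples; translational entropy will be noisy")
    tree = cKDTree(x)
    dist, _ = tree.query(x, k=k + 1)
    r = np.clip(dist[:, k], 1e-12, None)
    # H = psi(N) - psi(k) + ln V_3 + 3<ln r>  (nats)
    h = digamma(n) - digamma(k) + math.log(4.0 * math.pi / 3.0) + 3.0 * np.mean(np.log(r))
    return KB * temperature * (-h - math.log(bulk_density))


def _quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def site_orientational_entropy(
    orientations: np.ndarray,
    water_symmetry: int = 2,
    temperature: float = 300.0,
    k: int = 1,
) -> float:
    """−TΔS_orient (kcal/mol) from unit-quaternion orientation samples.

    Nearest-neighbour estimator on the rotation manifold with the geodesic
    metric (rotation angle).  The reference state is the uniform
    distribution over orientations reduced by the molecular symmetry number
    (2 for water): the measure of a geodesic ball of radius r is
    σ(r − sin r)/π under normalized Haar measure.  Returns ≈0 for uniform
    samples and a positive value for concentrated (ordered) ensembles;
    coincident samples saturate the estimator (capped, with a warning).
    """
    q = np.asarray(orientations, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError("orientations must be (n, 4) quaternions")
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("orientations must be unit quaternions")
    n = q.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    if n < 50:
        warnings.warn(f"only {n} samples; orientational entropy will be noisy")

    # |cos(theta/2)| between all pairs, maximized over symmetry images
    dots = np.abs(q @ q.T)
    if water_symmetry == 2:
        q_sym = _quat_multiply(q, WATER_C2_QUAT[None, :])
        dots = np.maximum(dots, np.abs(q @ q_sym.T))
    elif water_symmetry != 1:
        raise ValueError("water_symmetry must be 1 or 2")
    np.fill_diagonal(dots, -np.inf)
    # kth largest dot = kth nearest neighbour (self sits at -inf)
    part = np.partition(dots, n - k, axis=1)[:, n - k]
    theta = 2.0 * np.arccos(np.clip(part, -1.0, 1.0))
    saturated = theta < 1e-5
    if np.any(saturated):
        warnings.warn(
            f"{int(saturated.sum())} coincident orientation samples; "
            "estimator saturated at its cap")
        theta = np.clip(theta, 1e-5, None)
    mu = np.minimum(1.0, water_symmetry * (theta - np.sin(theta)) / math.pi)
    mu = np.clip(mu, 1e-30, None)  # resolution floor of the estimator
    h_rel = digamma(n) - digamma(k) + np.mean(np.log(mu))
    return KB * temperature * (-h_rel)


def site_entropy(
    oxygen_positions: np.ndarray,
    orientations: np.ndarray | None,
    bulk_density: float,
    temperature: float = 300.0,
    k: int = 1,
) -> SiteEntropy:
    """Combined first-order translational + orientational −TΔS for one site."""
    tr = site_translational_entropy(oxygen_positions, bulk_density,
                                    temperature=temperature, k=k)
    if orientations is None or len(orientations) == 0:
        orient = 0.0
    else:
        orient = site_orientational_entropy(orientations,
                                            temperature=temperature, k=k)
    return SiteEntropy(translational=tr, orientational=orient,
                       temperature=temperature)


def water_orientation_quaternion(water_coords: np.ndarray) -> np.ndarray:
    """Unit quaternion of a rigid 3-site water's orientation.

    ``water_coords`` is (3, 3) as (O, H1, H2).  The orientation maps the
    reference template (H bisector along +z, H1-H2 separation along x) onto
    the observed geometry; the H-labelling ambiguity corresponds to the C2
    symmetry handled by the estimator.
    """
    o, h1, h2 = np.asarray(water_coords, dtype=float)
    z = (h1 - o) + (h2 - o)
    z = z / np.linalg.norm(z)
    x = h1 - h2
    x -= z * np.dot(x, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    rot = np.column_stack([x, y, z])
    return _matrix_to_quaternion(rot)


def _matrix_to_quaternion(m: np.ndarray) -> np.ndarray:
    t = np.trace(m)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        w = 0.25 * s
        x = (m[2, 1] - m[1, 2]) / s
        y = (m[0, 2] - m[2, 0]) / s
        z = (m[1, 0] - m[0, 1]) / s
    elif m[0, 0] > m[1, 1] and m[0, 0] > m[2, 2]:
        s = math.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
        w = (m[2, 1] - m[1, 2]) / s
        x = 0.25 * s
        y = (m[0, 1] + m[1, 0]) / s
        z = (m[0, 2] + m[2, 0]) / s
    elif m[1, 1] > m[2, 2]:
        s = math.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
        w = (m[0, 2] - m[2, 0]) / s
        x = (m[0, 1] + m[1, 0]) / s
        y = 0.25 * s
        z = (m[1, 2] + m[2, 1]) / s
    else:
        s = math.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
        w = (m[1, 0] - m[0, 1]) / s
        x = (m[0, 2] + m[2, 0]) / s
        y = (m[1, 2] + m[2, 1]) / s
        z = 0.25 * s
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)
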