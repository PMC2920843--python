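"""Synthetic systems and trajectories with known statistical structure.

Three generators feed the test surface of every downstream stage:

* :func:`gen_water_box` — equilibrium configurations of a periodic box of
  rigid 3-site (TIP3P-parameter) waters sampled by single-molecule
  Metropolis Monte Carlo.  The observable of interest downstream (mean
  per-water interaction enthalpy) is purely configurational, so MC sampling
  stands in for molecular dynamics at desk scale.
* :func:`gen_tethered_waters` — waters tethered at well-separated sites
  with Gaussian translational spread, a concentrated orientational
  distribution, and Bernoulli per-frame occupancy; closed-form /
  quadrature-tabulated excess entropies are returned as ground truth.
* :func:`gen_toy_complex` — a rigid charged-LJ receptor plus a small
  flexible ligand with mainchain/sidechain structure and recorded
  force-field constants, so every MM energy is brute-force checkable.
* :func:`gen_hbond_fixture` — a minimal receptor/ligand/water geometry with
  exactly one direct and one water-bridged hydrogen bond by construction.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import quad

from .mm import COULOMB_K, KB
from .model_io import (
    AtomRecord,
    Dihedral,
    ParameterizedSystem,
    Trajectory,
    assign_parameters,
    read_parameter_table,
)

logger = logging.getLogger(__name__)

WATER_MOLAR_MASS = 18.01528  # g/mol
AVOGADRO = 6.02214076e23

# Rigid 3-site water geometry: O-H 0.9572 Å, H-O-H 104.52 deg.
_OH = 0.9572
_HOH = math.radians(104.52)
WATER_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],
        [_OH * math.sin(_HOH / 2), 0.0, _OH * math.cos(_HOH / 2)],
        [-_OH * math.sin(_HOH / 2), 0.0, _OH * math.cos(_HOH / 2)],
    ]
)

# TIP3P parameters (mm and parse charge sets kept identical for waters;
# PB radii are PARSE-style, SASA radii vdW-style).
TIP3P_TABLE_TEXT = """\
residue atom element mass mm_charge parse_charge lj_epsilon lj_rmin_half radius_pb radius_sasa
TIP3 OH2 O 15.9994 -0.834 -0.834 0.1521 1.76824 1.40 1.768
TIP3 H1  H 1.008    0.417  0.417  0.0    0.0     1.00 0.0
TIP3 H2  H 1.008    0.417  0.417  0.0    0.0     1.00 0.0
"""

_Q_O = -0.834
_Q_H = 0.417
_EPS_OO = 0.1521
_RMIN_OO = 2 * 1.76824


def tip3p_table() -> dict:
    return read_parameter_table(TIP3P_TABLE_TEXT)


def water_box_edge(n_waters: int, density: float) -> float:
    """Cubic box edge (Å) holding ``n_waters`` at ``density`` g/cm³."""
    if density <= 0:
        raise ValueError("density must be > 0")
    volume_cm3 = n_waters * WATER_MOLAR_MASS / (AVOGADRO * density)
    return (volume_cm3) ** (1.0 / 3.0) * 1e8


def _water_system(n_waters: int) -> ParameterizedSystem:
    atoms = []
    for m in range(n_waters):
        for name, element in (("OH2", "O"), ("H1", "H"), ("H2", "H")):
            atoms.append(
                AtomRecord(
                    serial=len(atoms), name=name, element=element,
                    residue_name="TIP3", residue_index=m + 1, chain_id="W",
                    is_water=True,
                )
            )
    system = ParameterizedSystem(atoms=atoms)
    return assign_parameters(system, tip3p_table())


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def _mol_energy(pos: np.ndarray, i: int, box: float, rc: float) -> float:
    """Energy of molecule i with all others; O-O min-image molecular cutoff."""
    n = pos.shape[0]
    rc2 = rc * rc
    e = 0.0
    for j in range(n):
        if j == i:
            continue
        sx = pos[j, 0, 0] - pos[i, 0, 0]
        sy = pos[j, 0, 1] - pos[i, 0, 1]
        sz = pos[j, 0, 2] - pos[i, 0, 2]
        shx = -box * round(sx / box)
        shy = -box * round(sy / box)
        shz = -box * round(sz / box)
        dox = sx + shx
        doy = sy + shy
        doz = sz + shz
        r2oo = dox * dox + doy * doy + doz * doz
        if r2oo > rc2:
            continue
        # LJ on O-O
        sr6 = (_RMIN_OO * _RMIN_OO / r2oo) ** 3
        e += _EPS_OO * (sr6 * sr6 - 2.0 * sr6)
        # Coulomb over all 9 site pairs, same image shift
        for a in range(3):
            qa = _Q_O if a == 0 else _Q_H
            for b in range(3):
                qb = _Q_O if b == 0 else _Q_H
                dx = pos[j, b, 0] + shx - pos[i, a, 0]
                dy = pos[j, b, 1] + shy - pos[i, a, 1]
                dz = pos[j, b, 2] + shz - pos[i, a, 2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                e += COULOMB_K * qa * qb / r
    return e


@njit(cache=True)
def _total_energy(pos: np.ndarray, box: float, rc: float) -> float:
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        e += _mol_energy(pos, i, box, rc)
    return 0.5 * e


@njit(cache=True)
def _mc_run(pos: np.ndarray, box: float, beta: float, rc: float,
            max_attempts: int, target_accepts: int,
            dt: float, dr: float) -> tuple[int, int]:
    """Single-molecule translation+rotation Metropolis moves, in place."""
    n = pos.shape[0]
    attempts = 0
    accepts = 0
    old = np.empty((3, 3))
    while attempts < max_attempts and accepts < target_accepts:
        i = np.random.randint(0, n)
        old[:, :] = pos[i]
        e_old = _mol_energy(pos, i, box, rc)
        # translation
        tx = (np.random.random() * 2.0 - 1.0) * dt
        ty = (np.random.random() * 2.0 - 1.0) * dt
        tz = (np.random.random() * 2.0 - 1.0) * dt
        # rotation about the oxygen (Rodrigues)
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        if norm < 1e-12:
            ax, ay, az, norm = 1.0, 0.0, 0.0, 1.0
        ax /= norm
        ay /= norm
        az /= norm
        ang = (np.random.random() * 2.0 - 1.0) * dr
        c = math.cos(ang)
        s = math.sin(ang)
        ox, oy, oz = pos[i, 0, 0], pos[i, 0, 1], pos[i, 0, 2]
        for a in range(1, 3):
            vx = pos[i, a, 0] - ox
            vy = pos[i, a, 1] - oy
            vz = pos[i, a, 2] - oz
            dot = ax * vx + ay * vy + az * vz
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            pos[i, a, 0] = ox + vx * c + cx * s + ax * dot * (1 - c)
            pos[i, a, 1] = oy + vy * c + cy * s + ay * dot * (1 - c)
            pos[i, a, 2] = oz + vz * c + cz * s + az * dot * (1 - c)
        for a in range(3):
            pos[i, a, 0] += tx
            pos[i, a, 1] += ty
            pos[i, a, 2] += tz
        # wrap the whole molecule so O stays in the primary box
        wx = box * math.floor(pos[i, 0, 0] / box)
        wy = box * math.floor(pos[i, 0, 1] / box)
        wz = box * math.floor(pos[i, 0, 2] / box)
        for a in range(3):
            pos[i, a, 0] -= wx
            pos[i, a, 1] -= wy
            pos[i, a, 2] -= wz
        e_new = _mol_energy(pos, i, box, rc)
        attempts += 1
        de = e_new - e_old
        if de <= 0.0 or np.random.random() < math.exp(-beta * de):
            accepts += 1
        else:
            pos[i] = old
    return attempts, accepts


def gen_water_box(
    n_waters: int = 216,
    density: float = 0.997,
    temperature: float = 300.0,
    n_snapshots: int = 200,
    n_equil_moves: int | None = None,
    seed: int = 0,
    cutoff: float = 8.5,
    translation_step: float = 0.15,
    rotation_step: float = 0.25,
) -> tuple[ParameterizedSystem, Trajectory]:
    """Sample equilibrium configurations of a periodic box of 3-site waters.

    Configurations are generated by single-molecule translation/rotation
    Metropolis moves with a molecule-based (O-O) minimum-image cutoff of
    ``cutoff`` Å.  Snapshots are decorrelated by at least ``n_waters``
    accepted moves.  ``n_equil_moves`` defaults to 500 attempted sweeps.
    """
    if n_waters < 8:
        raise ValueError("need at least 8 waters")
    if density <= 0:
        raise ValueError("density must be > 0")
    box = water_box_edge(n_waters, density)
    beta = 1.0 / (KB * temperature)
    if n_equil_moves is None:
        n_equil_moves = 500 * n_waters

    rng = np.random.default_rng(seed)
    # simple-cubic start with random orientations
    m = int(math.ceil(n_waters ** (1.0 / 3.0)))
    spacing = box / m
    pos = np.empty((n_waters, 3, 3))
    k = 0
    for ix in range(m):
        for iy in range(m):
            for iz in range(m):
                if k >= n_waters:
                    break
                center = (np.array([ix, iy, iz]) + 0.5) * spacing
                rot = _random_rotation(rng)
                pos[k] = center + WATER_TEMPLATE @ rot.T
                k += 1
    _seed_rng(int(rng.integers(0, 2**31 - 1)))
    att, acc = _mc_run(pos, box, beta, cutoff, int(n_equil_moves),
                       2**62, translation_step, rotation_step)
    logger.info("water-box equilibration: %d/%d moves accepted (%.1f%%)",
                acc, att, 100.0 * acc / max(att, 1))

    frames = np.empty((n_snapshots, n_waters * 3, 3))
    tot_att = tot_acc = 0
    for snap in range(n_snapshots):
        a, c = _mc_run(pos, box, beta, cutoff, 2000 * n_waters, n_waters,
                       translation_step, rotation_step)
        tot_att += a
        tot_acc += c
        frames[snap] = pos.reshape(-1, 3)
    logger.info("water-box production: acceptance %.1f%% over %d moves",
                100.0 * tot_acc / max(tot_att, 1), tot_att)

    system = _water_system(n_waters)
    system.coordinates = frames[0].copy()
    traj = Trajectory(coordinates=frames, frame_interval=1.0,
                      box=np.array([box, box, box]),
                      provenance=(f"MC water box n={n_waters} rho={density} "
                                  f"T={temperature} acc="
                                  f"{tot_acc / max(tot_att, 1):.3f}"))
    return system, traj


def total_configuration_energy(trajectory: Trajectory, cutoff: float = 8.5) -> np.ndarray:
    """Total MC potential energy of each water-box frame (sampler's cutoff)."""
    box = float(trajectory.frame_box(0)[0])
    n_w = trajectory.n_atoms // 3
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        out[f] = _total_energy(trajectory.coordinates[f].reshape(n_w, 3, 3),
                               box, cutoff)
    return out


# ---------------------------------------------------------------------------
# Tethered hydration-site waters
# ---------------------------------------------------------------------------


@dataclass
class TetheredSiteSpec:
    """Ground-truth description of one synthetic hydration site."""

    center: tuple[float, float, float]
    translational_sigma: float = 0.3  # Å
    orientational_concentration: float = 0.0  # vMF kappa; 0 = uniform
    occupancy_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.translational_sigma <= 0:
            raise ValueError("translational_sigma must be > 0")
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in [0, 1]")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return quaternion_to_matrix(q)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def sample_vmf_s3(kappa: float, n: int, rng: np.random.Generator,
                  mu: np.ndarray | None = None) -> np.ndarray:
    """Sample unit quaternions from a von Mises-Fisher density on S³.

    Wood's rejection algorithm for dimension p = 4.  ``kappa = 0`` gives
    uniform samples.
    """
    if mu is None:
        mu = np.array([1.0, 0.0, 0.0, 0.0])
    if kappa == 0.0:
        q = rng.normal(size=(n, 4))
        return q / np.linalg.norm(q, axis=1, keepdims=True)
    p = 4
    b = (-2 * kappa + math.sqrt(4 * kappa**2 + (p - 1) ** 2)) / (p - 1)
    x0 = (1 - b) / (1 + b)
    c = kappa * x0 + (p - 1) * math.log(1 - x0 * x0)
    ws = np.empty(n)
    filled = 0
    while filled < n:
        z = rng.beta((p - 1) / 2.0, (p - 1) / 2.0, size=n)
        u = rng.random(size=n)
        w = (1 - (1 + b) * z) / (1 - (1 - b) * z)
        ok = kappa * w + (p - 1) * np.log1p(-x0 * w) - c >= np.log(u)
        take = min(n - filled, int(ok.sum()))
        ws[filled:filled + take] = w[ok][:take]
        filled += take
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # orthonormal frame completing mu
    basis = _complete_basis(mu)  # (3, 4) rows orthogonal to mu
    tangent = v @ basis  # (n, 4) orthogonal to mu
    return ws[:, None] * mu[None, :] + np.sqrt(1 - ws[:, None] ** 2) * tangent


def _complete_basis(mu: np.ndarray) -> np.ndarray:
    """3 orthonormal vectors in R⁴ orthogonal to mu, rows of the result."""
    a = np.eye(4)
    vecs = [mu / np.linalg.norm(mu)]
    for col in a:
        w = col - sum(np.dot(col, v) * v for v in vecs)
        n = np.linalg.norm(w)
        if n > 1e-8:
            vecs.append(w / n)
        if len(vecs) == 4:
            break
    return np.array(vecs[1:])


def vmf_orientational_excess_entropy(
    kappa: float, temperature: float = 300.0, symmetry: int = 2
) -> float:
    """Quadrature oracle for -TΔS_orient of the vMF orientation ensemble.

    The vMF(kappa) density on unit quaternions induces a rotation density
    g(θ) ∝ cosh(κ cos(θ/2)) relative to the Haar measure, where θ is the
    rotation angle to the reference.  The returned value is
    k_B·T·(KL(p‖uniform) − ln σ) with σ the molecular symmetry number —
    valid for κ = 0 (exactly 0) or a concentrated mode (κ ≳ 15) whose
    symmetry images do not overlap; between those regimes the separated-mode
    assumption underestimates the entropy and no oracle value is tabulated.
    """
    if kappa == 0.0:
        return 0.0

    def haar_weight(theta: float) -> float:
        return (2.0 / math.pi) * math.sin(theta / 2.0) ** 2

    def g_unnorm(theta: float) -> float:
        return math.cosh(kappa * math.cos(theta / 2.0))

    z, _ = quad(lambda t: haar_weight(t) * g_unnorm(t), 0.0, math.pi, limit=200)
    kl, _ = quad(
        lambda t: haar_weight(t) * (g_unnorm(t) / z) * math.log(g_unnorm(t) / z),
        0.0, math.pi, limit=200,
    )
    return KB * temperature * (kl - math.log(symmetry))


def gaussian_translational_excess_entropy(
    sigma: float, bulk_density: float, temperature: float = 300.0
) -> float:
    """Closed-form -TΔS_trans = -k_B·T·⟨ln(ρ_site/ρ_bulk)⟩ for a Gaussian site.

    ρ_site is the probability density of the occupying-water oxygen position,
    an isotropic Gaussian with per-axis standard deviation ``sigma``.
    """
    h_gauss = 1.5 * math.log(2.0 * math.pi * math.e * sigma * sigma)
    return KB * temperature * (-h_gauss - math.log(bulk_density))


def gen_tethered_waters(
    sites: list[TetheredSiteSpec],
    n_frames: int = 2000,
    bulk_density: float = 0.0334,
    temperature: float = 300.0,
    seed: int = 0,
) -> tuple[ParameterizedSystem, Trajectory, list[dict]]:
    """Waters tethered at isolated sites, with analytic site thermodynamics.

    Each frame, each site is occupied with its ``occupancy_prob``; the water
    oxygen is drawn from an isotropic Gaussian around the site center and
    the orientation from a vMF distribution about a fixed reference (uniform
    when the concentration is 0).  Frames where a site is unoccupied park
    that water far outside the scene (500 Å away) so the atom count stays
    constant.  Returns the per-site ground truth: occupancy probability and
    closed-form/quadrature translational and orientational −TΔS.
    """
    centers = np.array([s.center for s in sites], dtype=float)
    if len(sites) > 1:
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 6.0:
            raise ValueError(f"site centers closer than 6 Å (min {d.min():.2f})")
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    system = _water_system(n_sites)
    coords = np.empty((n_frames, n_sites * 3, 3))
    truth = []
    for si, spec in enumerate(sites):
        occupied = rng.random(n_frames) < spec.occupancy_prob
        oxy = centers[si] + rng.normal(scale=spec.translational_sigma,
                                       size=(n_frames, 3))
        quats = sample_vmf_s3(spec.orientational_concentration, n_frames, rng)
        park = centers[si] + 500.0 + 50.0 * si
        for f in range(n_frames):
            if occupied[f]:
                rot = quaternion_to_matrix(quats[f])
                mol = oxy[f] + WATER_TEMPLATE @ rot.T
            else:
                mol = park + WATER_TEMPLATE
            coords[f, 3 * si:3 * si + 3] = mol
        truth.append(
            {
                "center": tuple(spec.center),
                "occupancy": spec.occupancy_prob,
                "mTdS_trans": gaussian_translational_excess_entropy(
                    spec.translational_sigma, bulk_density, temperature),
                "mTdS_orient": vmf_orientational_excess_entropy(
                    spec.orientational_concentration, temperature),
                "occupied_frames": occupied,
            }
        )
    traj = Trajectory(coordinates=coords, frame_interval=10.0,
                      provenance=f"tethered sites n={n_sites} seed={seed}")
    return system, traj, truth


# ---------------------------------------------------------------------------
# Toy receptor-ligand complex
# ---------------------------------------------------------------------------

_LIG_ATOMS = (("N", "N", 14.007), ("CA", "C", 12.011), ("C", "C", 12.011),
              ("CB", "C", 12.011), ("CG", "C", 12.011))


def gen_toy_complex(
    n_ligand_residues: int = 3,
    seed: int = 0,
    n_frames: int = 100,
    jitter: float = 0.06,
    degenerate_unbound: bool = False,
) -> tuple[ParameterizedSystem, Trajectory, Trajectory]:
    """A rigid charged-LJ receptor with a small flexible peptide-like ligand.

    The ligand has ``n_ligand_residues`` residues of five atoms each
    (N/CA/C mainchain, CB/CG sidechain), one sidechain dihedral per residue,
    and bonds recorded so nonbonded exclusions are well defined.  Bound
    frames are Gaussian jitter (sigma ``jitter`` Å) about the docked pose;
    unbound frames jitter about a relaxed, displaced pose with rotated
    sidechains (or about the docked pose itself when
    ``degenerate_unbound``).  Returns (system, bound, unbound) trajectories
    over the full atom order.
    """
    if not 2 <= n_ligand_residues <= 6:
        raise ValueError("n_ligand_residues must be in [2, 6]")
    rng = np.random.default_rng(seed)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    # receptor: 20 sites on a wobbly spherical shell, net charge ~0
    n_rec = 20
    charges = rng.uniform(-0.25, 0.25, size=n_rec)
    charges -= charges.mean()
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i in range(n_rec):
        zf = 1 - 2 * (i + 0.5) / n_rec
        r = math.sqrt(max(0.0, 1 - zf * zf))
        theta = golden * i
        pnt = 5.0 * np.array([r * math.cos(theta), r * math.sin(theta), zf])
        pnt += rng.normal(scale=0.3, size=3)
        atoms.append(AtomRecord(serial=len(atoms), name=f"R{i}", element="C",
                                residue_name="REC", residue_index=1,
                                chain_id="A", mass=12.011,
                                mm_charge=float(charges[i]),
                                parse_charge=float(charges[i]),
                                lj_epsilon=0.1, lj_rmin_half=1.9,
                                radius_pb=1.9, radius_sasa=1.9))
        coords.append(pnt)
    receptor_idx = np.arange(n_rec)

    bonds: list[tuple[int, int]] = []
    dihedrals: list[Dihedral] = []
    lig_start = len(atoms)
    prev_c = None
    for res in range(n_ligand_residues):
        base = np.array([8.5, -1.5 + 3.2 * res, 0.0])
        offsets = {
            "N": np.array([0.0, 0.0, 0.0]),
            "CA": np.array([1.0, 1.0, 0.0]),
            "C": np.array([0.0, 2.0, 0.0]),
            "CB": np.array([2.2, 1.0, 0.9]),
            "CG": np.array([3.0, 1.2, 2.1]),
        }
        res_idx = {}
        for name, element, mass in _LIG_ATOMS:
            q = float(rng.uniform(-0.3, 0.3))
            atoms.append(AtomRecord(serial=len(atoms), name=name,
                                    element=element, residue_name="TOY",
                                    residue_index=res + 1, chain_id="B",
                                    mass=mass, mm_charge=q, parse_charge=q,
                                    lj_epsilon=0.08, lj_rmin_half=1.8,
                                    radius_pb=1.8, radius_sasa=1.8))
            coords.append(base + offsets[name])
            res_idx[name] = len(atoms) - 1
        bonds += [(res_idx["N"], res_idx["CA"]), (res_idx["CA"], res_idx["C"]),
                  (res_idx["CA"], res_idx["CB"]), (res_idx["CB"], res_idx["CG"])]
        if prev_c is not None:
            bonds.append((prev_c, res_idx["N"]))
        prev_c = res_idx["C"]
        dihedrals.append(Dihedral(res_idx["N"], res_idx["CA"], res_idx["CB"],
                                  res_idx["CG"], force_k=0.8, periodicity=3,
                                  phase=0.0))
    ligand_idx = np.arange(lig_start, len(atoms))

    system = ParameterizedSystem(atoms=atoms, coordinates=np.asarray(coords),
                                 bonds=bonds, dihedrals=dihedrals)
    system.set_selection("receptor", receptor_idx)
    system.set_selection("ligand", ligand_idx)

    docked = np.asarray(coords)
    if degenerate_unbound:
        relaxed = docked.copy()
    else:
        relaxed = docked.copy()
        relaxed[ligand_idx] += np.array([100.0, 0.0, 0.0])
        # relax sidechains: rotate each CG about the CA-CB axis by 40 deg
        for d in dihedrals:
            ca, cb, cg = d.j, d.k, d.l
            axis = relaxed[cb] - relaxed[ca]
            axis /= np.linalg.norm(axis)
            v = relaxed[cg] - relaxed[cb]
            ang = math.radians(40.0)
            relaxed[cg] = relaxed[cb] + (
                v * math.cos(ang) + np.cross(axis, v) * math.sin(ang)
                + axis * np.dot(axis, v) * (1 - math.cos(ang)))

    def _jittered(pose: np.ndarray) -> np.ndarray:
        frames = np.repeat(pose[None], n_frames, axis=0)
        frames[:, ligand_idx] += rng.normal(scale=jitter,
                                            size=(n_frames, ligand_idx.size, 3))
        return frames

    bound = Trajectory(coordinates=_jittered(docked), frame_interval=10.0,
                       provenance=f"toy complex bound seed={seed}")
    unbound = Trajectory(coordinates=_jittered(relaxed), frame_interval=10.0,
                         provenance=f"toy complex unbound seed={seed}")
    return system, bound, unbound


# ---------------------------------------------------------------------------
# Hydrogen-bond census fixture
# ---------------------------------------------------------------------------


def gen_hbond_fixture(
    include_bridge: bool = True,
    stretch_direct: bool = False,
) -> tuple[ParameterizedSystem, dict]:
    """Receptor/ligand/water geometry with known hydrogen-bond census.

    Defaults give exactly one direct receptor-ligand hydrogen bond and one
    bridging water (H-bonded to both sides) under the package's default
    criteria (d_DA ≤ 3.5 Å, D-H-A ≥ 120°).  ``stretch_direct`` moves the
    direct acceptor past the distance cutoff; ``include_bridge=False``
    removes the bridging water.  Returns (system, ground-truth counts).
    """
    direct_acceptor_z = 4.2 if stretch_direct else 2.9
    spec = [
        # receptor: amide donor + carbonyl acceptor
        ("N", "N", "REC", 1, "A", (0.0, 0.0, 0.0)),
        ("H", "H", "REC", 1, "A", (0.0, 0.0, 1.01)),
        ("C", "C", "REC", 1, "A", (6.0, -1.3, -0.4)),
        ("O", "O", "REC", 1, "A", (6.0, 0.0, 0.0)),
        # ligand: acceptor opposite the receptor amide + its own donor
        ("OD1", "O", "LIG", 1, "B", (0.0, 0.0, direct_acceptor_z)),
        ("CD", "C", "LIG", 1, "B", (0.0, 1.2, direct_acceptor_z + 0.6)),
        ("ND", "N", "LIG", 1, "B", (6.0, 0.0, 5.7)),
        ("HD", "H", "LIG", 1, "B", (6.0, 0.0, 4.69)),
    ]
    if include_bridge:
        spec += [
            ("OH2", "O", "HOH", 1, "W", (6.0, 0.0, 2.8)),
            ("H1", "H", "HOH", 1, "W", (6.0, 0.0, 1.84)),
            ("H2", "H", "HOH", 1, "W", (6.929, 0.0, 3.040)),
        ]
    atoms = []
    coords = []
    for i, (name, element, resname, resid, chain, xyz) in enumerate(spec):
        atoms.append(AtomRecord(serial=i, name=name, element=element,
                                residue_name=resname, residue_index=resid,
                                chain_id=chain, is_water=(resname == "HOH")))
        coords.append(xyz)
    system = ParameterizedSystem(atoms=atoms, coordinates=np.asarray(coords))
    system.set_selection("receptor", [i for i, a in enumerate(atoms)
                                      if a.residue_name == "REC"])
    system.set_selection("ligand", [i for i, a in enumerate(atoms)
                                    if a.residue_name == "LIG"])
    truth = {"direct": 0 if stretch_direct else 1,
             "bridged": 1 if include_bridge else 0}
    return system, truth
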