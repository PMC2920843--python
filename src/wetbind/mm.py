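"""Molecular-mechanics nonbonded and torsional energy terms.

Electrostatics use Coulomb's law with the CHARMM constant
k_e = 332.0637 kcal·Å/(mol·e²); van der Waals terms use the
Lennard-Jones Rmin/epsilon convention with Lorentz-Berthelot style
combining (Rmin_ij = Rmin_half_i + Rmin_half_j, eps_ij = sqrt(eps_i eps_j)).
No cutoff is applied: binding-energy terms are evaluated exactly on finite
snapshots.  Solute-solute interaction terms default to a uniform dielectric
of 2.0 (interior screening); explicit-solvent water energies use 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Dihedral, ParameterizedSystem, Trajectory

COULOMB_K = 332.0637  # kcal·Å/(mol·e²)
KB = 0.0019872041  # kcal/(mol·K)


class NearSingularityError(ValueError):
    """Two atoms closer than the hard floor; names the pair."""


class GeometryError(ValueError):
    """Undefined internal coordinate (e.g. colinear dihedral atoms)."""


@dataclass
class EnergyBreakdown:
    """Energy terms for one group pair (or one group) on one frame."""

    vdw: float = 0.0
    elec: float = 0.0
    torsion: float = 0.0
    context: str = ""
    residue_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def total(self) -> float:
        return self.vdw + self.elec + self.torsion


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def pairwise_nonbonded(
    system: ParameterizedSystem,
    group_a: np.ndarray,
    group_b: np.ndarray,
    frame: np.ndarray,
    dielectric: float = 1.0,
    box: np.ndarray | None = None,
    residue_matrix: bool = False,
) -> EnergyBreakdown:
    """Exact double-sum Coulomb + LJ energy between two disjoint groups.

    Optionally also returns a residue-pair energy matrix (vdw+elec) indexed
    by the order of residues appearing within each group.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("empty selection")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups overlap")
    q = system.mm_charges()
    eps, rmh = system.lj_params()
    ra = frame[group_a]
    rb = frame[group_b]
    d = ra[:, None, :] - rb[None, :, :]
    if box is not None:
        d = _min_image(d, np.asarray(box, dtype=float))
    r = np.sqrt(np.sum(d * d, axis=-1))
    if np.any(r < 1e-4):
        ia, ib = np.argwhere(r < 1e-4)[0]
        raise NearSingularityError(
            f"atoms {group_a[ia]} and {group_b[ib]} at r={r[ia, ib]:.2e} Å"
        )
    elec_mat = COULOMB_K * np.outer(q[group_a], q[group_b]) / (dielectric * r)
    eps_ij = np.sqrt(np.outer(eps[group_a], eps[group_b]))
    rmin_ij = rmh[group_a][:, None] + rmh[group_b][None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(rmin_ij > 0, (rmin_ij / r) ** 6, 0.0)
    vdw_mat = eps_ij * (sr6 * sr6 - 2.0 * sr6)
    out = EnergyBreakdown(vdw=float(vdw_mat.sum()), elec=float(elec_mat.sum()),
                          context="pairwise")
    if residue_matrix:
        keys_a = [system.atoms[i].residue_key for i in group_a]
        keys_b = [system.atoms[i].residue_key for i in group_b]
        ua = list(dict.fromkeys(keys_a))
        ub = list(dict.fromkeys(keys_b))
        mat = np.zeros((len(ua), len(ub)))
        ia = np.array([ua.index(k) for k in keys_a])
        ib = np.array([ub.index(k) for k in keys_b])
        np.add.at(mat, (ia[:, None], ib[None, :]), elec_mat + vdw_mat)
        out.residue_matrix = mat
    return out


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed dihedral angle in radians for four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < 1e-10 or n2n < 1e-10:
        raise GeometryError("colinear atoms: dihedral undefined")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def torsion_energy(
    system: ParameterizedSystem,
    frame: np.ndarray,
    selection: np.ndarray,
) -> float:
    """Sum of k(1 + cos(n*phi - delta)) over dihedrals internal to selection."""
    sel = set(int(i) for i in np.asarray(selection).ravel())
    total = 0.0
    for d in system.dihedrals:
        if {d.i, d.j, d.k, d.l} <= sel:
            phi = dihedral_angle(frame[d.i], frame[d.j], frame[d.k], frame[d.l])
            total += d.force_k * (1.0 + np.cos(d.periodicity * phi - d.phase))
    return total


def interaction_energy(
    system: ParameterizedSystem,
    receptor: np.ndarray,
    ligand: np.ndarray,
    trajectory: Trajectory,
    dielectric: float = 2.0,
) -> list[EnergyBreakdown]:
    """Receptor-ligand MM interaction energy (vdw + elec) per frame.

    Water atoms must already be excluded from both selections; explicit
    solvent never enters the binding-energy MM terms.
    """
    receptor = np.asarray(receptor, dtype=int)
    ligand = np.asarray(ligand, dtype=int)
    if receptor.size == 0 or ligand.size == 0:
        raise ValueError("empty selection")
    for sel in (receptor, ligand):
        if any(system.atoms[i].is_water for i in sel):
            raise ValueError("water atoms must be excluded from interaction selections")
    series = []
    for f in range(trajectory.n_frames):
        e = pairwise_nonbonded(system, receptor, ligand,
                               trajectory.coordinates[f], dielectric=dielectric)
        e.context = f"interaction frame {f}"
        series.append(e)
    return series


def build_exclusions(
    system: ParameterizedSystem, selection: np.ndarray
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """(excluded 1-2/1-3 pairs, 1-4 pairs) within a selection, from bonds."""
    sel = set(int(i) for i in np.asarray(selection).ravel())
    adj: dict[int, set[int]] = {i: set() for i in sel}
    for i, j in system.bonds:
        if i in sel and j in sel:
            adj[i].add(j)
            adj[j].add(i)
    excluded: set[tuple[int, int]] = set()
    pairs14: set[tuple[int, int]] = set()
    for i in sel:
        for j in adj[i]:  # 1-2
            excluded.add((min(i, j), max(i, j)))
            for k in adj[j]:  # 1-3
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
                for l in adj[k]:  # 1-4
                    if l not in (i, j) and l != k:
                        pairs14.add((min(i, l), max(i, l)))
    pairs14 -= excluded
    return excluded, pairs14


def internal_energy(
    system: ParameterizedSystem,
    selection: np.ndarray,
    trajectory: Trajectory,
    dielectric: float = 2.0,
    scale14: float = 1.0,
) -> np.ndarray:
    """Intra-group elec + vdw + torsion per frame, honouring exclusions.

    Bonded (1-2) and 1-3 pairs contribute nothing; 1-4 pairs are scaled by
    ``scale14`` (default 1.0, i.e. full strength).
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    excluded, pairs14 = build_exclusions(system, sel)
    q = system.mm_charges()
    eps, rmh = system.lj_params()
    ii, jj = np.triu_indices(sel.size, k=1)
    ai, aj = sel[ii], sel[jj]
    pair_keys = [(min(a, b), max(a, b)) for a, b in zip(ai, aj)]
    scale = np.ones(len(pair_keys))
    for p, key in enumerate(pair_keys):
        if key in excluded:
            scale[p] = 0.0
        elif key in pairs14:
            scale[p] = scale14
    qq = q[ai] * q[aj]
    eps_ij = np.sqrt(eps[ai] * eps[aj])
    rmin_ij = rmh[ai] + rmh[aj]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        coords = trajectory.coordinates[f]
        d = coords[ai] - coords[aj]
        r = np.sqrt(np.sum(d * d, axis=-1))
        live = scale > 0
        if np.any(r[live] < 1e-4):
            bad = np.flatnonzero(live & (r < 1e-4))[0]
            raise NearSingularityError(
                f"atoms {ai[bad]} and {aj[bad]} at r={r[bad]:.2e} Å (frame {f})"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            elec = np.where(live, COULOMB_K * qq / (dielectric * r), 0.0)
            sr6 = np.where(live & (rmin_ij > 0), (rmin_ij / np.where(r > 0, r, 1.0)) ** 6, 0.0)
        vdw = eps_ij * (sr6 * sr6 - 2.0 * sr6)
        out[f] = float(np.sum(scale * (elec + vdw))) + torsion_energy(system, coords, sel)
    return out


def deformation_penalty(
    bound: np.ndarray,
    unbound: np.ndarray,
    bound_sem: float = 0.0,
    unbound_sem: float = 0.0,
) -> tuple[float, float]:
    """Ligand deformation penalty: mean(bound) - mean(unbound) internal energy.

    Returns (value, sem) with the two block SEMs combined in quadrature.
    """
    bound = np.asarray(bound, dtype=float)
    unbound = np.asarray(unbound, dtype=float)
    if bound.size == 0 or unbound.size == 0:
        raise ValueError("empty internal-energy series")
    value = float(bound.mean() - unbound.mean())
    sem = float(np.hypot(bound_sem, unbound_sem))
    return value, sem


def water_environment_energy(
    system: ParameterizedSystem,
    water_residue: tuple[str, int, str] | int,
    frame: np.ndarray,
    dielectric: float = 1.0,
    box: np.ndarray | None = None,
) -> float:
    """Full nonbonded energy of one water molecule with everything else.

    The sum runs over every atom outside the water (Coulomb + LJ, not
    halved), with minimum-image convention when a periodic box is given.
    An isolated water returns 0.
    """
    groups = system.residue_atoms()
    if isinstance(water_residue, int):
        keys = system.water_residues()
        key = keys[water_residue] if water_residue < len(keys) else None
        if key is None:
            raise KeyError(f"no water residue with ordinal {water_residue}")
    else:
        key = water_residue
    widx = groups[key]
    other = np.setdiff1d(np.arange(system.n_atoms), widx)
    if other.size == 0:
        return 0.0
    e = pairwise_nonbonded(system, widx, other, frame,
                           dielectric=dielectric, box=box)
    return e.vdw + e.elec


def environment_energies_all_waters(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    dielectric: float = 1.0,
) -> np.ndarray:
    """Per-frame, per-water environment energies for an all-water system.

    Vectorised fast path used by the bulk-water reference; result has shape
    (n_frames, n_waters).  Equivalent to calling
    :func:`water_environment_energy` water by water.
    """
    keys = system.water_residues()
    groups = system.residue_atoms()
    n_w = len(keys)
    idx = np.array([groups[k] for k in keys])  # (n_w, atoms_per_water)
    if idx.shape[0] != n_w:
        raise ValueError("ragged water residues")
    q = system.mm_charges()[idx]  # (n_w, s)
    eps, rmh = system.lj_params()
    eps_w = eps[idx]
    rmh_w = rmh[idx]
    out = np.empty((trajectory.n_frames, n_w))
    s = idx.shape[1]
    for f in range(trajectory.n_frames):
        box = trajectory.frame_box(f)
        coords = trajectory.coordinates[f][idx]  # (n_w, s, 3)
        # pair displacement between all water pairs, all site pairs
        d = coords[:, None, :, None, :] - coords[None, :, None, :, :]
        if box is not None:
            d = _min_image(d, np.asarray(box, dtype=float))
        r = np.sqrt(np.sum(d * d, axis=-1))  # (n_w, n_w, s, s)
        ar = np.arange(n_w)
        r[ar, ar] = np.inf  # mask self-molecule pairs
        elec = COULOMB_K / dielectric * (q[:, None, :, None] * q[None, :, None, :]) / r
        eps_ij = np.sqrt(eps_w[:, None, :, None] * eps_w[None, :, None, :])
        rmin_ij = rmh_w[:, None, :, None] + rmh_w[None, :, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = np.where(rmin_ij > 0, (rmin_ij / r) ** 6, 0.0)
        vdw = eps_ij * (sr6 * sr6 - 2.0 * sr6)
        out[f] = np.sum(elec + vdw, axis=(1, 2, 3))
    return out
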