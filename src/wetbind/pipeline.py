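"""Assembly of MM-PBSA binding free energies over trajectory snapshots.

The binding free energy is assembled per snapshot as

    ΔG = ΔH + (−TΔS),   ΔH = E_vdw + E_elec + ΔE_deformation + ΔG_PB + ΔG_SA

where E_vdw/E_elec are receptor-ligand molecular-mechanics interaction
terms, ΔE_deformation is the ligand's internal-energy difference between
the bound and unbound ensembles (the protein's internal energy is never
differenced), ΔG_PB the continuum-electrostatic desolvation penalty and
ΔG_SA the surface-area nonpolar term.  Uncertainty on each ensemble mean
is the block standard error over 20 equal contiguous blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mm, pb
from .model_io import (
    MAINCHAIN_ATOM_NAMES,
    ParameterizedSystem,
    Trajectory,
)


@dataclass
class MMPBSASettings:
    dielectric: float = 2.0  # solute-solute MM electrostatics
    stride: float = 10.0  # ps between analysed snapshots
    scale14: float = 1.0  # 1-4 nonbonded scaling in internal energies
    include_pb: bool = True
    include_sasa: bool = True
    pb: pb.PBSettings = field(default_factory=pb.PBSettings)
    sasa_probe: float = 1.4
    sasa_points: int = 960
    n_blocks: int = 20


@dataclass
class BindingFreeEnergyTable:
    """Aggregated binding free energy components (kcal/mol, SEM where defined)."""

    vdw: float
    elec: float
    desolvation: float  # ΔG_PB
    sasa_term: float  # ΔG_SA
    deformation: float
    vdw_sem: float = math.nan
    elec_sem: float = math.nan
    desolvation_sem: float = math.nan
    sasa_sem: float = math.nan
    deformation_sem: float = math.nan
    minus_t_delta_s: float | None = None

    @property
    def dH(self) -> float:
        return (self.vdw + self.elec + self.desolvation + self.sasa_term
                + self.deformation)

    @property
    def dG(self) -> float | None:
        if self.minus_t_delta_s is None:
            return None
        return self.dH + self.minus_t_delta_s

    def delta_delta(self, reference: "BindingFreeEnergyTable") -> dict[str, float]:
        """ΔΔ values of this ligand versus a reference ligand, unrounded."""
        out = {"ddH": self.dH - reference.dH}
        if self.dG is not None and reference.dG is not None:
            out["ddG"] = self.dG - reference.dG
            out["d_mTdS"] = self.minus_t_delta_s - reference.minus_t_delta_s
        return out

    def to_series(self) -> pd.Series:
        data = {
            "VDW": self.vdw, "Electrostatic": self.elec,
            "Desolvation": self.desolvation, "SASA": self.sasa_term,
            "Deformation": self.deformation, "dH": self.dH,
        }
        if self.minus_t_delta_s is not None:
            data["-TdS"] = self.minus_t_delta_s
            data["dG"] = self.dG
        return pd.Series(data)


def block_sem(series: np.ndarray, n_blocks: int = 20) -> float:
    """Block standard error of the mean of a per-snapshot series.

    The series is split into ``n_blocks`` equal contiguous blocks (any
    remainder at the end is truncated); the SEM is the standard deviation
    of the block means divided by sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if x.size < n_blocks:
        raise ValueError(f"series of length {x.size} shorter than {n_blocks} blocks")
    if np.all(x == x[0]):
        return 0.0
    m = x.size // n_blocks
    means = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))


def snapshot_indices(n_frames: int, frame_interval: float, stride: float) -> np.ndarray:
    """Frame indices at ``stride`` ps spacing; floor(duration/stride) snapshots."""
    duration = n_frames * frame_interval
    if stride > duration:
        raise ValueError(f"stride {stride} ps exceeds duration {duration} ps")
    count = int(math.floor(duration / stride + 1e-9))
    step = stride / frame_interval
    idx = np.round((np.arange(1, count + 1) * step)).astype(int) - 1
    return np.clip(idx, 0, n_frames - 1)


def _strip_waters(system: ParameterizedSystem, sel: np.ndarray) -> np.ndarray:
    sel = np.asarray(sel, dtype=int)
    return sel[[not system.atoms[i].is_water for i in sel]]


@dataclass
class MMPBSAResult:
    records: pd.DataFrame  # per-snapshot component series
    table: BindingFreeEnergyTable
    snapshot_frames: np.ndarray


def run_mmpbsa(
    system: ParameterizedSystem,
    complex_traj: Trajectory,
    unbound_ligand_traj: Trajectory,
    receptor: np.ndarray,
    ligand: np.ndarray,
    settings: MMPBSASettings | None = None,
    minus_t_delta_s: float | None = None,
) -> MMPBSAResult:
    """Full MM-PBSA binding-energy calculation over trajectory snapshots.

    Waters are stripped from both selections before any term is computed.
    The ligand deformation penalty differences the ligand's internal energy
    between the complex and unbound trajectories; the receptor's internal
    energy is never differenced.
    """
    settings = settings or MMPBSASettings()
    receptor = _strip_waters(system, receptor)
    ligand = _strip_waters(system, ligand)
    idx_c = snapshot_indices(complex_traj.n_frames, complex_traj.frame_interval,
                             settings.stride)
    idx_u = snapshot_indices(unbound_ligand_traj.n_frames,
                             unbound_ligand_traj.frame_interval, settings.stride)

    sub_c = Trajectory(complex_traj.coordinates[idx_c],
                       frame_interval=settings.stride)
    sub_u = Trajectory(unbound_ligand_traj.coordinates[idx_u],
                       frame_interval=settings.stride)

    inter = mm.interaction_energy(system, receptor, ligand, sub_c,
                                  dielectric=settings.dielectric)
    vdw = np.array([e.vdw for e in inter])
    elec = np.array([e.elec for e in inter])

    internal_bound = mm.internal_energy(system, ligand, sub_c,
                                        dielectric=settings.dielectric,
                                        scale14=settings.scale14)
    internal_unbound = mm.internal_energy(system, ligand, sub_u,
                                          dielectric=settings.dielectric,
                                          scale14=settings.scale14)

    data = {"frame": idx_c, "vdw": vdw, "elec": elec,
            "internal_bound": internal_bound}
    complex_idx = np.concatenate([receptor, ligand])
    if settings.include_pb:
        data["pb"] = pb.delta_g_pb(system, complex_idx, receptor, ligand,
                                   sub_c.coordinates, settings.pb)
    if settings.include_sasa:
        dsasa = np.empty(sub_c.n_frames)
        for f in range(sub_c.n_frames):
            frame = sub_c.coordinates[f]
            _, s_c = pb.sasa(system, complex_idx, frame,
                             probe=settings.sasa_probe,
                             n_sphere_points=settings.sasa_points)
            _, s_r = pb.sasa(system, receptor, frame,
                             probe=settings.sasa_probe,
                             n_sphere_points=settings.sasa_points)
            _, s_l = pb.sasa(system, ligand, frame,
                             probe=settings.sasa_probe,
                             n_sphere_points=settings.sasa_points)
            dsasa[f] = s_c - s_r - s_l
        data["delta_sasa"] = dsasa
    records = pd.DataFrame(data)

    nb = settings.n_blocks
    def sem(x: np.ndarray) -> float:
        return block_sem(x, nb) if len(x) >= nb else math.nan

    deform, deform_sem = mm.deformation_penalty(
        internal_bound, internal_unbound,
        sem(internal_bound), sem(internal_unbound))
    pb_mean = float(records["pb"].mean()) if settings.include_pb else 0.0
    pb_sem = sem(records["pb"].to_numpy()) if settings.include_pb else math.nan
    if settings.include_sasa:
        sa_series = np.array([pb.delta_g_sa(d) for d in dsasa])
        sa_mean, sa_sem = float(sa_series.mean()), sem(sa_series)
    else:
        sa_mean, sa_sem = 0.0, math.nan
    table = BindingFreeEnergyTable(
        vdw=float(vdw.mean()), elec=float(elec.mean()),
        desolvation=pb_mean, sasa_term=sa_mean, deformation=deform,
        vdw_sem=sem(vdw), elec_sem=sem(elec), desolvation_sem=pb_sem,
        sasa_sem=sa_sem, deformation_sem=deform_sem,
        minus_t_delta_s=minus_t_delta_s,
    )
    return MMPBSAResult(records=records, table=table, snapshot_frames=idx_c)


def assemble_binding_free_energy(
    components: dict[str, float] | BindingFreeEnergyTable,
    minus_t_delta_s: float,
) -> BindingFreeEnergyTable:
    """Attach the conformational-entropy term and assemble ΔG = ΔH + (−TΔS).

    ``components`` carries the enthalpy terms (keys ``vdw``, ``elec``,
    ``desolvation``, ``sasa``, ``deformation``); a missing component raises
    with the absent names listed.
    """
    if isinstance(components, BindingFreeEnergyTable):
        return replace(components, minus_t_delta_s=minus_t_delta_s)
    required = ["vdw", "elec", "desolvation", "sasa", "deformation"]
    missing = [k for k in required if k not in components]
    if missing:
        raise KeyError(f"missing components: {', '.join(missing)}")
    return BindingFreeEnergyTable(
        vdw=components["vdw"], elec=components["elec"],
        desolvation=components["desolvation"], sasa_term=components["sasa"],
        deformation=components["deformation"],
        minus_t_delta_s=minus_t_delta_s,
    )


def static_mmpbsa(
    system: ParameterizedSystem,
    complex_frame: np.ndarray,
    relaxed_ligand_frame: np.ndarray,
    receptor: np.ndarray,
    ligand: np.ndarray,
    settings: MMPBSASettings | None = None,
) -> MMPBSAResult:
    """Single-point MM-PBSA on a (complex, relaxed-ligand) structure pair.

    Equivalent to :func:`run_mmpbsa` on one-frame trajectories; the
    deformation penalty is the ligand internal-energy difference between
    the bound frame and the pre-relaxed unbound frame.  No entropy term.
    """
    settings = settings or MMPBSASettings()
    settings = replace(settings, stride=1.0)
    bound = Trajectory(np.asarray(complex_frame)[None], frame_interval=1.0)
    unbound = Trajectory(np.asarray(relaxed_ligand_frame)[None], frame_interval=1.0)
    return run_mmpbsa(system, bound, unbound, receptor, ligand, settings)


# ---------------------------------------------------------------------------
# Per-residue decomposition
# ---------------------------------------------------------------------------


def ligand_residue_groups(
    system: ParameterizedSystem, ligand: np.ndarray
) -> dict[str, np.ndarray]:
    """Sidechain group per ligand residue plus one pooled mainchain group."""
    ligand = np.asarray(ligand, dtype=int)
    groups: dict[str, list[int]] = {"Mainchain": []}
    for i in ligand:
        a = system.atoms[i]
        if a.name in MAINCHAIN_ATOM_NAMES:
            groups["Mainchain"].append(i)
        else:
            label = f"{a.residue_name} {a.residue_index}"
            groups.setdefault(label, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in groups.items() if v}


def _group_internal_series(
    system: ParameterizedSystem,
    ligand: np.ndarray,
    traj: Trajectory,
    groups: dict[str, np.ndarray],
    dielectric: float,
    scale14: float,
) -> dict[str, np.ndarray]:
    """Per-frame intra-ligand energy attributed to groups.

    Nonbonded pair energies are split in half between the two partners'
    groups when they differ; torsion energies are split equally over the
    four dihedral atoms.  Group series sum to the whole-ligand internal
    energy by construction.
    """
    sel = np.asarray(ligand, dtype=int)
    excluded, pairs14 = mm.build_exclusions(system, sel)
    group_of = {}
    for g, idxs in groups.items():
        for i in idxs:
            group_of[int(i)] = g
    q = system.mm_charges()
    eps, rmh = system.lj_params()
    ii, jj = np.triu_indices(sel.size, k=1)
    ai, aj = sel[ii], sel[jj]
    scale = np.ones(ai.size)
    for p, key in enumerate(zip(np.minimum(ai, aj), np.maximum(ai, aj))):
        key = (int(key[0]), int(key[1]))
        if key in excluded:
            scale[p] = 0.0
        elif key in pairs14:
            scale[p] = scale14
    qq = q[ai] * q[aj]
    eps_ij = np.sqrt(eps[ai] * eps[aj])
    rmin_ij = rmh[ai] + rmh[aj]
    names = list(groups)
    out = {g: np.zeros(traj.n_frames) for g in names}
    ga = np.array([names.index(group_of[int(a)]) for a in ai])
    gb = np.array([names.index(group_of[int(a)]) for a in aj])
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        d = coords[ai] - coords[aj]
        r = np.sqrt(np.sum(d * d, axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            elec = np.where(scale > 0, mm.COULOMB_K * qq / (dielectric * r), 0.0)
            sr6 = np.where((scale > 0) & (rmin_ij > 0), (rmin_ij / r) ** 6, 0.0)
        pair_e = scale * (elec + eps_ij * (sr6 * sr6 - 2.0 * sr6))
        acc = np.zeros(len(names))
        same = ga == gb
        np.add.at(acc, ga[same], pair_e[same])
        np.add.at(acc, ga[~same], 0.5 * pair_e[~same])
        np.add.at(acc, gb[~same], 0.5 * pair_e[~same])
        sel_set = set(int(s) for s in sel)
        for dih in system.dihedrals:
            if {dih.i, dih.j, dih.k, dih.l} <= sel_set:
                phi = mm.dihedral_angle(coords[dih.i], coords[dih.j],
                                        coords[dih.k], coords[dih.l])
                e = dih.force_k * (1.0 + np.cos(dih.periodicity * phi - dih.phase))
                for atom in (dih.i, dih.j, dih.k, dih.l):
                    acc[names.index(group_of[atom])] += e / 4.0
        for g, name in enumerate(names):
            out[name][f] = acc[g]
    return out


def per_residue_decomposition(
    system: ParameterizedSystem,
    complex_traj: Trajectory,
    unbound_ligand_traj: Trajectory,
    receptor: np.ndarray,
    ligand: np.ndarray,
    settings: MMPBSASettings | None = None,
    groups: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-residue (sidechain) + pooled-mainchain contribution table.

    Interaction terms are attributed to each ligand residue's sidechain
    group and to the pooled mainchain; intramolecular (deformation)
    cross-group pair energies are split half-and-half between the partner
    groups; the per-group PB desolvation deletes every other ligand atom
    while keeping the receptor and the grid geometry of the full-complex
    run (so the PB column need not sum to the whole-ligand value); the
    per-residue SASA term omits the 0.92 constant.  The percent column is
    each group total over the grand total × 100.
    """
    settings = settings or MMPBSASettings()
    receptor = _strip_waters(system, receptor)
    ligand = _strip_waters(system, ligand)
    if groups is None:
        groups = ligand_residue_groups(system, ligand)
    covered = np.sort(np.concatenate(list(groups.values())))
    if not np.array_equal(covered, np.sort(ligand)):
        raise ValueError("residue partition does not cover the ligand")
    idx_c = snapshot_indices(complex_traj.n_frames, complex_traj.frame_interval,
                             settings.stride)
    idx_u = snapshot_indices(unbound_ligand_traj.n_frames,
                             unbound_ligand_traj.frame_interval, settings.stride)
    sub_c = Trajectory(complex_traj.coordinates[idx_c], frame_interval=settings.stride)
    sub_u = Trajectory(unbound_ligand_traj.coordinates[idx_u],
                       frame_interval=settings.stride)

    nb = settings.n_blocks
    def sem(x: np.ndarray) -> float:
        return block_sem(x, nb) if len(x) >= nb else math.nan

    rows = {}
    for name, gidx in groups.items():
        inter = mm.interaction_energy(system, receptor, gidx, sub_c,
                                      dielectric=settings.dielectric)
        vdw = np.array([e.vdw for e in inter])
        elec = np.array([e.elec for e in inter])
        rows[name] = {"vdw": float(vdw.mean()), "vdw_sem": sem(vdw),
                      "elec": float(elec.mean()), "elec_sem": sem(elec)}

    bound_groups = _group_internal_series(system, ligand, sub_c, groups,
                                          settings.dielectric, settings.scale14)
    unbound_groups = _group_internal_series(system, ligand, sub_u, groups,
                                            settings.dielectric, settings.scale14)
    for name in groups:
        rows[name]["deformation"] = float(bound_groups[name].mean()
                                          - unbound_groups[name].mean())

    radii = np.array([a.radius_pb for a in system.atoms])
    complex_idx = np.concatenate([receptor, ligand])
    for name, gidx in groups.items():
        if settings.include_pb:
            vals = np.empty(sub_c.n_frames)
            for f in range(sub_c.n_frames):
                frame = sub_c.coordinates[f]
                grids = pb.focusing_grids(frame[complex_idx], radii[complex_idx],
                                          settings.pb)
                part = np.concatenate([receptor, gidx])
                g_part = pb.pb_solvation_energy(system, part, settings.pb,
                                                positions=frame,
                                                grids=grids).solvation_energy
                g_rec = pb.pb_solvation_energy(system, receptor, settings.pb,
                                               positions=frame,
                                               grids=grids).solvation_energy
                g_res = pb.pb_solvation_energy(system, gidx, settings.pb,
                                               positions=frame,
                                               grids=grids).solvation_energy
                vals[f] = g_part - g_rec - g_res
            rows[name]["desolvation"] = float(vals.mean())
        else:
            rows[name]["desolvation"] = 0.0
        if settings.include_sasa:
            vals = np.empty(sub_c.n_frames)
            for f in range(sub_c.n_frames):
                frame = sub_c.coordinates[f]
                per_c, _ = pb.sasa(system, complex_idx, frame,
                                   probe=settings.sasa_probe,
                                   n_sphere_points=settings.sasa_points)
                per_l, _ = pb.sasa(system, ligand, frame,
                                   probe=settings.sasa_probe,
                                   n_sphere_points=settings.sasa_points)
                in_complex = {int(a): per_c[p] for p, a in enumerate(complex_idx)}
                alone = {int(a): per_l[p] for p, a in enumerate(ligand)}
                vals[f] = sum(in_complex[int(a)] - alone[int(a)] for a in gidx)
            rows[name]["sasa"] = pb.SASA_SLOPE * float(vals.mean())
        else:
            rows[name]["sasa"] = 0.0

    df = pd.DataFrame(rows).T
    df["total"] = df[["vdw", "elec", "deformation", "desolvation", "sasa"]].sum(axis=1)
    grand = df["total"].sum()
    df["percent"] = 100.0 * df["total"] / grand
    order = [n for n in df.index if n == "Mainchain"] + \
        [n for n in df.index if n != "Mainchain"]
    return df.loc[order]
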