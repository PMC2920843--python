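"""Hydration-site thermodynamics at protein surfaces.

Water-oxygen density over a trajectory is clustered into discrete
hydration sites; each site is characterized by its occupancy, mean
hydrogen-bond count, enthalpy relative to bulk water (mean nonbonded
energy of the occupying water with the rest of the system, minus the bulk
reference) and first-order excess entropy (translational + orientational,
reported as −TΔS).  Comparing apo- and bound-state site lists classifies
sites as displaced (eliminated by ligand overlap; the water returns to
bulk, so binding gains the negative of the apo excess free energy),
stabilized (matched site present in both states) or unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import entropy as entropy_mod
from . import mm
from .model_io import ParameterizedSystem, Trajectory
from .pipeline import block_sem
from .structure import HBondCriteria, water_hbond_count

logger = logging.getLogger(__name__)

BULK_WATER_NUMBER_DENSITY = 0.0334  # Å⁻³ at 0.997 g/cm³


@dataclass
class HydrationSite:
    """One clustered water site; thermodynamics are relative to bulk water.

    ``dH``, ``mTdS`` and ``dG`` are raw per-water values; the
    occupancy-weighted counterparts multiply each by the site occupancy.
    ``dG = dH + mTdS`` holds exactly by construction.
    """

    center: np.ndarray
    radius: float
    occupancy: float = math.nan
    mean_hbonds: float = math.nan
    dH: float = math.nan
    mTdS_trans: float = math.nan
    mTdS_orient: float = math.nan
    label: str = ""
    n_samples: int = 0

    @property
    def mTdS(self) -> float:
        return self.mTdS_trans + self.mTdS_orient

    @property
    def dG(self) -> float:
        return self.dH + self.mTdS

    @property
    def weighted_dH(self) -> float:
        return self.occupancy * self.dH

    @property
    def weighted_mTdS(self) -> float:
        return self.occupancy * self.mTdS

    @property
    def weighted_dG(self) -> float:
        return self.occupancy * self.dG


@dataclass
class SiteComparison:
    """Apo-vs-bound pairing of one apo hydration site.

    ΔΔ values are of binding, from occupancy-weighted site values:
    displaced sites return their water to bulk (ΔΔX = −apo X); stabilized
    sites difference bound − apo.
    """

    apo: HydrationSite
    bound: HydrationSite | None
    classification: str  # displaced | stabilized | unchanged
    ddH: float
    d_mTdS: float

    @property
    def ddG(self) -> float:
        return self.ddH + self.d_mTdS


@dataclass
class BulkReference:
    value: float  # kcal/mol per water
    sem: float
    n_samples: int


def cluster_hydration_sites(
    oxygen_positions: np.ndarray,
    n_frames: int,
    site_radius: float = 1.0,
    exclusion_radius: float = 2.4,
    min_occupancy: float = 0.25,
) -> list[HydrationSite]:
    """Greedy density clustering of water-oxygen samples into sites.

    Repeatedly takes the sample with the most neighbours within
    ``site_radius`` as a site center (ties broken by lexicographically
    smallest position, making the result invariant to frame order), removes
    every sample within ``exclusion_radius``, and stops when the best
    remaining count drops below ``min_occupancy * n_frames``.  Returns
    centers only; thermodynamics are filled by :func:`characterize_site`.
    """
    x = np.asarray(oxygen_positions, dtype=float).reshape(-1, 3)
    if n_frames < 100:
        logger.warning("clustering on %d frames; occupancies will be coarse",
                       n_frames)
    sites: list[HydrationSite] = []
    if x.shape[0] == 0:
        return sites
    threshold = min_occupancy * n_frames
    alive = np.ones(x.shape[0], dtype=bool)
    while True:
        pts = x[alive]
        if pts.shape[0] == 0:
            break
        tree = cKDTree(pts)
        counts = np.array([len(nb) for nb in tree.query_ball_point(pts, site_radius)])
        best = counts.max()
        if best < threshold:
            break
        cand = np.flatnonzero(counts == best)
        order = np.lexsort((pts[cand, 2], pts[cand, 1], pts[cand, 0]))
        center = pts[cand[order[0]]]
        sites.append(HydrationSite(center=center.copy(), radius=site_radius))
        kill = np.linalg.norm(x - center, axis=1) <= exclusion_radius
        alive &= ~kill
    return sites


def _water_oxygen_indices(system: ParameterizedSystem) -> tuple[list, np.ndarray]:
    """(water residue keys, their oxygen atom indices) in matching order."""
    keys = system.water_residues()
    groups = system.residue_atoms()
    oxy = []
    for k in keys:
        osel = [i for i in groups[k] if system.atoms[i].element == "O"]
        if len(osel) != 1:
            raise ValueError(f"water {k} does not have exactly one oxygen")
        oxy.append(osel[0])
    return keys, np.asarray(oxy, dtype=int)


def collect_region_oxygens(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    center: np.ndarray | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """All water-oxygen positions over all frames (optionally within a sphere)."""
    _, oxy = _water_oxygen_indices(system)
    pos = trajectory.coordinates[:, oxy].reshape(-1, 3)
    if center is not None and radius is not None:
        keep = np.linalg.norm(pos - np.asarray(center), axis=1) <= radius
        pos = pos[keep]
    return pos


def characterize_site(
    site: HydrationSite,
    system: ParameterizedSystem,
    trajectory: Trajectory,
    bulk_ref: float,
    hbond_criteria: HBondCriteria | None = None,
    temperature: float = 300.0,
    bulk_density: float = BULK_WATER_NUMBER_DENSITY,
    dielectric: float = 1.0,
    knn: int = 1,
) -> HydrationSite:
    """Fill in occupancy, H-bonds, ΔH, −TΔS and ΔG for one site.

    Occupancy counts frames with at least one water oxygen inside the site
    radius (the nearest is taken when several are present).  ΔH is the mean
    environment energy of the occupying water minus ``bulk_ref``; −TΔS
    comes from the nearest-neighbour estimators on the occupying samples.
    """
    criteria = hbond_criteria or HBondCriteria()
    keys, oxy = _water_oxygen_indices(system)
    groups = system.residue_atoms()
    center = np.asarray(site.center, dtype=float)
    energies, hbonds, positions, quats = [], [], [], []
    occupied = 0
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        d = np.linalg.norm(frame[oxy] - center, axis=1)
        w = int(np.argmin(d))
        if d[w] > site.radius:
            continue
        occupied += 1
        key = keys[w]
        box = trajectory.frame_box(f)
        energies.append(mm.water_environment_energy(system, key, frame,
                                                    dielectric=dielectric, box=box))
        hbonds.append(water_hbond_count(system, frame, key, criteria))
        positions.append(frame[oxy[w]])
        widx = groups[key]
        if len(widx) == 3:
            quats.append(entropy_mod.water_orientation_quaternion(frame[widx]))
    if occupied == 0:
        raise ValueError(f"site at {center} never occupied; thermodynamics undefined")
    occupancy = occupied / trajectory.n_frames
    se = entropy_mod.site_entropy(np.asarray(positions),
                                  np.asarray(quats) if quats else None,
                                  bulk_density, temperature=temperature, k=knn)
    site.occupancy = occupancy
    site.mean_hbonds = float(np.mean(hbonds))
    site.dH = float(np.mean(energies)) - bulk_ref
    site.mTdS_trans = se.translational
    site.mTdS_orient = se.orientational
    site.n_samples = occupied
    return site


def probe_site_analysis(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    point: np.ndarray | tuple[tuple[int, int], float],
    bulk_ref: float,
    probe_radius: float = 1.4,
    dielectric: float = 1.0,
    n_blocks: int = 20,
) -> tuple[float, float, float]:
    """Occupancy and mean enthalpy (vs bulk) of a fixed probe sphere.

    ``point`` is either a coordinate triple or ``((i, j), distance)``: a
    point ``distance`` Å from atom i along the i→j direction, resolved per
    frame.  Every water oxygen within ``probe_radius`` contributes its
    environment energy.  Returns (occupancy, mean ΔH, SEM); the enthalpy is
    NaN when no frame is occupied.  The SEM uses the 20-block rule over the
    per-frame means of occupied frames when enough are available.
    """
    keys, oxy = _water_oxygen_indices(system)
    per_frame: list[float] = []
    occupied = 0
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        if isinstance(point, tuple) and len(point) == 2 and np.ndim(point[0]) == 1:
            (i, j), dist = point
            u = frame[j] - frame[i]
            p = frame[i] + dist * u / np.linalg.norm(u)
        else:
            p = np.asarray(point, dtype=float)
        d = np.linalg.norm(frame[oxy] - p, axis=1)
        hits = np.flatnonzero(d <= probe_radius)
        if hits.size == 0:
            continue
        occupied += 1
        box = trajectory.frame_box(f)
        vals = [mm.water_environment_energy(system, keys[w], frame,
                                            dielectric=dielectric, box=box)
                for w in hits]
        per_frame.append(float(np.mean(vals)))
    occupancy = occupied / trajectory.n_frames
    if occupied == 0:
        return occupancy, math.nan, math.nan
    series = np.asarray(per_frame) - bulk_ref
    sem = block_sem(series, n_blocks) if series.size >= n_blocks else math.nan
    return occupancy, float(series.mean()), sem


def bulk_reference(
    system: ParameterizedSystem,
    trajectory: Trajectory,
    center: np.ndarray | None = None,
    inner_radius: float | None = None,
    n_snapshots: int | None = None,
    dielectric: float = 1.0,
    n_blocks: int = 20,
) -> BulkReference:
    """Mean environment energy of a bulk water molecule.

    Averages the full nonbonded energy of each included water with its
    entire environment over ``n_snapshots`` frames (all frames by
    default).  ``center``/``inner_radius`` restrict to waters inside a
    sphere — the analogue of trimming surface waters from a droplet; for a
    periodic box all waters are bulk-like and no restriction is needed.
    """
    n_use = trajectory.n_frames if n_snapshots is None else min(
        n_snapshots, trajectory.n_frames)
    sub = Trajectory(trajectory.coordinates[:n_use],
                     frame_interval=trajectory.frame_interval,
                     box=trajectory.box)
    energies = mm.environment_energies_all_waters(system, sub,
                                                  dielectric=dielectric)
    if inner_radius is not None and center is not None:
        _, oxy = _water_oxygen_indices(system)
        c = np.asarray(center, dtype=float)
        mask = np.linalg.norm(sub.coordinates[:, oxy] - c, axis=2) <= inner_radius
        if not mask.any():
            raise ValueError("no waters inside the bulk selection sphere")
        per_frame = np.array([energies[f, mask[f]].mean()
                              if mask[f].any() else np.nan
                              for f in range(n_use)])
        per_frame = per_frame[~np.isnan(per_frame)]
        n_samples = int(mask.sum())
    else:
        per_frame = energies.mean(axis=1)
        n_samples = energies.size
    value = float(per_frame.mean())
    sem = block_sem(per_frame, n_blocks) if per_frame.size >= n_blocks else math.nan
    return BulkReference(value=value, sem=sem, n_samples=n_samples)


def compare_states(
    apo_sites: list[HydrationSite],
    bound_sites: list[HydrationSite],
    ligand_heavy_coords: np.ndarray,
    match_radius: float = 1.5,
    overlap_radius: float = 2.0,
) -> list[SiteComparison]:
    """Classify apo sites against the bound state and compute ΔΔ of binding.

    An apo site matched to a bound site within ``match_radius`` is
    stabilized (ΔΔX = bound X − apo X, occupancy-weighted); an unmatched
    apo site with a ligand heavy atom within ``overlap_radius`` is
    displaced (its water returns to bulk: ΔΔX = −apo X); anything else is
    unchanged.  Several apo sites matching one bound site resolve to the
    nearest (logged).
    """
    lig = np.asarray(ligand_heavy_coords, dtype=float).reshape(-1, 3)
    bound_centers = (np.array([s.center for s in bound_sites])
                     if bound_sites else np.empty((0, 3)))
    out: list[SiteComparison] = []
    claimed: dict[int, tuple[int, float]] = {}
    matches: list[int | None] = []
    for ai, apo in enumerate(apo_sites):
        match: int | None = None
        if len(bound_centers):
            d = np.linalg.norm(bound_centers - apo.center, axis=1)
            j = int(np.argmin(d))
            if d[j] <= match_radius:
                if j in claimed and claimed[j][1] <= d[j]:
                    logger.info("bound site %d already claimed by closer apo site %d",
                                j, claimed[j][0])
                else:
                    if j in claimed:
                        matches[claimed[j][0]] = None
                    claimed[j] = (ai, float(d[j]))
                    match = j
        matches.append(match)
    for apo, match in zip(apo_sites, matches):
        if match is not None:
            b = bound_sites[match]
            out.append(SiteComparison(
                apo=apo, bound=b, classification="stabilized",
                ddH=b.weighted_dH - apo.weighted_dH,
                d_mTdS=b.weighted_mTdS - apo.weighted_mTdS))
        elif lig.size and np.min(np.linalg.norm(lig - apo.center, axis=1)) <= overlap_radius:
            out.append(SiteComparison(
                apo=apo, bound=None, classification="displaced",
                ddH=-apo.weighted_dH, d_mTdS=-apo.weighted_mTdS))
        else:
            out.append(SiteComparison(apo=apo, bound=None,
                                      classification="unchanged",
                                      ddH=0.0, d_mTdS=0.0))
    return out


def aggregate_sites(
    rows: list[HydrationSite] | list[SiteComparison],
    by_label: bool = True,
) -> pd.DataFrame:
    """Subtotals and totals of occupancy-weighted site thermodynamics.

    For :class:`HydrationSite` rows: groups by ``label`` (e.g. the ligand
    residue a site overlaps) and sums weighted ΔH, −TΔS, ΔG, with a Total
    row.  For :class:`SiteComparison` rows: sums ΔΔH, Δ(−TΔS), ΔΔG over
    classifications with a Sum row.  Pure arithmetic over the input rows.
    """
    if not rows:
        return pd.DataFrame()
    if isinstance(rows[0], SiteComparison):
        data = [{"classification": r.classification, "ddH": r.ddH,
                 "d_mTdS": r.d_mTdS, "ddG": r.ddG} for r in rows]
        df = pd.DataFrame(data)
        total = pd.DataFrame([{"classification": "Sum",
                               "ddH": df["ddH"].sum(),
                               "d_mTdS": df["d_mTdS"].sum(),
                               "ddG": df["ddG"].sum()}])
        return pd.concat([df, total], ignore_index=True)
    data = [{"label": s.label or f"site{i}", "dH": s.weighted_dH,
             "mTdS": s.weighted_mTdS, "dG": s.weighted_dG}
            for i, s in enumerate(rows)]
    df = pd.DataFrame(data)
    if by_label:
        df = df.groupby("label", sort=False).sum().reset_index()
    total = pd.DataFrame([{"label": "Total", "dH": df["dH"].sum(),
                           "mTdS": df["mTdS"].sum(), "dG": df["dG"].sum()}])
    return pd.concat([df, total], ignore_index=True)
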