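"""Hydrogen-bond detection, interface census and RMSF analysis."""

from __future__ import annotations

import math
import urllib.request
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_io import ParameterizedSystem, Trajectory

POLAR_ELEMENTS = {"N", "O"}
_H_COVALENT_CUTOFF = 1.25  # Å, H bonded to its heavy atom


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    Defaults: donor-acceptor distance ≤ 3.5 Å and D-H-A angle ≥ 120°.
    When no hydrogens are present (crystal structures), the angle test is
    skipped and the distance criterion alone applies.
    """

    d_da: float = 3.5  # Å
    angle: float = 120.0  # degrees


@dataclass
class HBond:
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float | None


def _polar_atoms(system: ParameterizedSystem, frame: np.ndarray):
    """(donor -> hydrogens mapping, acceptor list) from element + proximity."""
    heavies = [i for i, a in enumerate(system.atoms) if a.element in POLAR_ELEMENTS]
    hydrogens = [i for i, a in enumerate(system.atoms) if a.element == "H"]
    donors: dict[int, list[int]] = {}
    if hydrogens:
        hpos = frame[hydrogens]
        for i in heavies:
            d = np.linalg.norm(hpos - frame[i], axis=1)
            att = [hydrogens[j] for j in np.flatnonzero(d <= _H_COVALENT_CUTOFF)
                   if system.atoms[hydrogens[j]].residue_key
                   == system.atoms[i].residue_key]
            if att:
                donors[i] = att
    return donors, heavies


def detect_hbonds(
    system: ParameterizedSystem,
    frame: np.ndarray | None = None,
    criteria: HBondCriteria | None = None,
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
) -> list[HBond]:
    """Geometric hydrogen bonds, sorted by (donor, acceptor) indices.

    Donors are N/O atoms with a covalently attached hydrogen (within
    1.25 Å in the same residue); acceptors are all N/O atoms.  ``donors`` /
    ``acceptors`` restrict the candidate index sets.  Without hydrogens
    the search runs in heavy-atom-only mode: every polar atom is a
    potential donor and the angle test is skipped.
    """
    criteria = criteria or HBondCriteria()
    coords = frame if frame is not None else system.coordinates
    if coords is None:
        raise ValueError("no coordinates")
    donor_map, polar = _polar_atoms(system, coords)
    heavy_only = not donor_map
    donor_ids = list(donor_map) if not heavy_only else list(polar)
    if donors is not None:
        allowed = set(int(i) for i in np.asarray(donors).ravel())
        donor_ids = [i for i in donor_ids if i in allowed]
    acceptor_ids = list(polar)
    if acceptors is not None:
        allowed = set(int(i) for i in np.asarray(acceptors).ravel())
        acceptor_ids = [i for i in acceptor_ids if i in allowed]
    bonds: list[HBond] = []
    for d in donor_ids:
        for a in acceptor_ids:
            if a == d:
                continue
            if system.atoms[a].residue_key == system.atoms[d].residue_key:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if dist > criteria.d_da:
                continue
            if heavy_only:
                bonds.append(HBond(d, None, a, dist, None))
                continue
            best = None
            for h in donor_map[d]:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if ang >= criteria.angle and (best is None or ang > best[1]):
                    best = (h, ang)
            if best is not None:
                bonds.append(HBond(d, best[0], a, dist, best[1]))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def water_hbond_count(
    system: ParameterizedSystem,
    frame: np.ndarray,
    water_key: tuple[str, int, str],
    criteria: HBondCriteria | None = None,
) -> int:
    """Number of hydrogen bonds one water makes with everything else."""
    widx = set(int(i) for i in system.residue_atoms()[water_key])
    count = 0
    for b in detect_hbonds(system, frame, criteria):
        in_w = (b.donor in widx) + (b.acceptor in widx)
        if in_w == 1:
            count += 1
    return count


def interface_hbond_census(
    system: ParameterizedSystem,
    receptor: np.ndarray,
    ligand: np.ndarray,
    frame: np.ndarray | None = None,
    criteria: HBondCriteria | None = None,
) -> tuple[int, int]:
    """(direct, water-bridged) hydrogen-bond counts across an interface.

    Direct: H-bonds with one partner atom in the receptor and one in the
    ligand.  Bridged: waters simultaneously H-bonded to at least one
    receptor atom and one ligand atom; each such water counts once
    regardless of how many partners it touches.
    """
    rec = set(int(i) for i in np.asarray(receptor).ravel())
    lig = set(int(i) for i in np.asarray(ligand).ravel())
    bonds = detect_hbonds(system, frame, criteria)
    direct = 0
    water_partners: dict[tuple, set[str]] = {}
    for b in bonds:
        ends = (b.donor, b.acceptor)
        sides = []
        for e in ends:
            if e in rec:
                sides.append("rec")
            elif e in lig:
                sides.append("lig")
            elif system.atoms[e].is_water:
                sides.append("wat")
            else:
                sides.append("other")
        if set(sides) == {"rec", "lig"}:
            direct += 1
        elif "wat" in sides and sides != ["wat", "wat"]:
            w = ends[sides.index("wat")]
            other = sides[1 - sides.index("wat")]
            if other in {"rec", "lig"}:
                water_partners.setdefault(
                    system.atoms[w].residue_key, set()).add(other)
    bridged = sum(1 for partners in water_partners.values()
                  if {"rec", "lig"} <= partners)
    return direct, bridged


def rmsf(
    trajectory: Trajectory,
    selection: np.ndarray,
    superpose: bool = False,
    masses: np.ndarray | None = None,
    window: int | None = None,
):
    """Per-atom root mean square fluctuation about the mean position.

    RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩).  With ``superpose`` each frame is
    first rigid-fit (mass-weighted when masses are given) onto the mean
    structure of the selection; water RMSF is conventionally computed
    without superposition.  ``window`` additionally returns a time series
    of per-window RMSF arrays over consecutive blocks of frames.
    """
    sel = np.asarray(selection, dtype=int)
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for an RMSF")
    frames = trajectory.coordinates[:, sel].copy()
    if superpose:
        from .entropy import _kabsch_weighted
        w = (np.asarray(masses, dtype=float)[sel]
             if masses is not None and np.ndim(masses) else
             np.ones(sel.size))
        ref = frames.mean(axis=0)
        for _ in range(3):
            for f in range(frames.shape[0]):
                frames[f] = _kabsch_weighted(frames[f], ref, w)
            ref = frames.mean(axis=0)

    def _rmsf(block: np.ndarray) -> np.ndarray:
        mean = block.mean(axis=0)
        return np.sqrt(np.mean(np.sum((block - mean) ** 2, axis=2), axis=0))

    overall = _rmsf(frames)
    if window is None:
        return overall
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    series = [_rmsf(frames[s:s + window])
              for s in range(0, frames.shape[0] - window + 1, window)]
    return overall, series


def fetch_pdb(pdb_id: str, cache_dir: str | Path = ".", timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB (cached); returns the local path."""
    pdb_id = pdb_id.upper()
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{pdb_id}.pdb"
    if target.exists():
        return target
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        target.write_bytes(resp.read())
    return target
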