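"""Structures, trajectories, parameter tables and atom selections.

All quantities use a single package-wide unit system: lengths in Å, energies
in kcal/mol, charges in elementary charge units, masses in amu, times in ps
and temperatures in K.  Internal atom indexing is 0-based; PDB serials are
1-based only at the file boundary.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# Residue names recognised as water unless overridden per call.
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP4", "SPC", "TP3"})

# Backbone atom names for amino-acid residues: N, CA, C, O, chain termini and
# the hydrogens bonded to those heavy atoms.  Everything else in a residue is
# sidechain.  The two sets partition each residue by construction.
MAINCHAIN_ATOM_NAMES = frozenset(
    {
        "N", "CA", "C", "O", "OXT", "OT1", "OT2",
        "H", "HN", "H1", "H2", "H3", "HT1", "HT2", "HT3",
        "HA", "HA1", "HA2", "HN1", "HN2",
    }
)


class PDBParseError(ValueError):
    """Malformed fixed-column record; message names the offending line."""


class SelectionError(KeyError):
    """Selection expression referenced something that does not exist."""


class MissingParameterError(KeyError):
    """Strict parameter assignment found atoms not covered by the tables."""


class TrajectoryShapeError(ValueError):
    """Trajectory atom count does not match the system."""


@dataclass
class AtomRecord:
    """One atom with coordinates handled separately by the owning system.

    Two charge sets coexist: ``mm_charge`` feeds molecular-mechanics energy
    terms, ``parse_charge`` feeds the continuum-electrostatics (PB) stage.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str = "A"
    insertion_code: str = ""
    mass: float = 0.0
    mm_charge: float = 0.0
    parse_charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    radius_pb: float = 0.0
    radius_sasa: float = 0.0
    is_water: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.insertion_code)


@dataclass
class Dihedral:
    """Proper torsion i-j-k-l with energy k*(1 + cos(n*phi - delta))."""

    i: int
    j: int
    k: int
    l: int
    force_k: float  # kcal/mol
    periodicity: int
    phase: float  # radians


@dataclass
class ParameterizedSystem:
    """Atoms, optional topology, coordinates and named index selections."""

    atoms: list[AtomRecord]
    coordinates: np.ndarray | None = None  # (n_atoms, 3) Å
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[Dihedral] = field(default_factory=list)
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (len(self.atoms), 3):
                raise TrajectoryShapeError(
                    f"coordinates shape {self.coordinates.shape} does not match "
                    f"{len(self.atoms)} atoms"
                )
        for d in self.dihedrals:
            for idx in (d.i, d.j, d.k, d.l):
                if not 0 <= idx < len(self.atoms):
                    raise IndexError(f"dihedral atom index {idx} out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # ---- residue bookkeeping -------------------------------------------------

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique residue keys (chain, index, insertion code)."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int, str], np.ndarray]:
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault(a.residue_key, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def water_residues(self) -> list[tuple[str, int, str]]:
        return [k for k, idx in self.residue_atoms().items()
                if all(self.atoms[i].is_water for i in idx)]

    # ---- selections ----------------------------------------------------------

    def set_selection(self, name: str, indices: Iterable[int]) -> None:
        idx = np.unique(np.asarray(list(indices), dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise SelectionError(f"selection '{name}' indices out of range")
        self.selections[name] = idx

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression to a sorted 0-based index array.

        The expression is a sequence of whitespace-separated terms, implicitly
        AND-ed.  Terms: a named role (``receptor``/``ligand``/``water`` or any
        registered selection), ``protein`` (non-water), ``mainchain``,
        ``sidechain``, ``heavy``, ``hydrogen``, ``resid N`` / ``resid N-M``
        (residue_index match), ``name X`` and ``resname X``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        tokens = expression.split()
        i = 0
        names = np.array([a.name for a in self.atoms])
        resnames = np.array([a.residue_name for a in self.atoms])
        resids = np.array([a.residue_index for a in self.atoms])
        elements = np.array([a.element for a in self.atoms])
        waters = np.array([a.is_water for a in self.atoms])
        while i < len(tokens):
            tok = tokens[i]
            if tok in self.selections:
                m = np.zeros(self.n_atoms, dtype=bool)
                m[self.selections[tok]] = True
            elif tok == "water":
                m = waters
            elif tok == "protein":
                m = ~waters
            elif tok == "mainchain":
                m = np.isin(names, list(MAINCHAIN_ATOM_NAMES)) & ~waters
            elif tok == "sidechain":
                m = ~np.isin(names, list(MAINCHAIN_ATOM_NAMES)) & ~waters
            elif tok == "heavy":
                m = elements != "H"
            elif tok == "hydrogen":
                m = elements == "H"
            elif tok in {"resid", "name", "resname"}:
                i += 1
                if i >= len(tokens):
                    raise SelectionError(f"'{tok}' requires an argument")
                arg = tokens[i]
                if tok == "resid":
                    if "-" in arg[1:]:  # "3-5" range; leading "-" is a sign
                        cut = arg.index("-", 1)
                        lo, hi = int(arg[:cut]), int(arg[cut + 1:])
                    else:
                        lo = hi = int(arg)
                    if not np.any((resids >= lo) & (resids <= hi)):
                        raise SelectionError(f"no residue with index in {arg}")
                    m = (resids >= lo) & (resids <= hi)
                elif tok == "name":
                    m = names == arg
                else:
                    m = resnames == arg
            else:
                raise SelectionError(f"unknown selection term '{tok}'")
            mask &= m
            i += 1
        return np.flatnonzero(mask)

    def copy(self) -> "ParameterizedSystem":
        return ParameterizedSystem(
            atoms=[replace(a) for a in self.atoms],
            coordinates=None if self.coordinates is None else self.coordinates.copy(),
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=[replace(d) for d in self.dihedrals],
            selections={k: v.copy() for k, v in self.selections.items()},
        )

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def mm_charges(self) -> np.ndarray:
        return np.array([a.mm_charge for a in self.atoms])

    def parse_charges(self) -> np.ndarray:
        return np.array([a.parse_charge for a in self.atoms])

    def lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        eps = np.array([a.lj_epsilon for a in self.atoms])
        rmh = np.array([a.lj_rmin_half for a in self.atoms])
        return eps, rmh


@dataclass
class Trajectory:
    """Ordered coordinate frames aligned to a system's atom order."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3) Å
    frame_interval: float  # ps
    box: np.ndarray | None = None  # (3,) or (n_frames, 3) Å, orthorhombic
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryShapeError(
                f"coordinates must be (n_frames, n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 ps")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame_box(self, frame: int) -> np.ndarray | None:
        if self.box is None:
            return None
        if self.box.ndim == 1:
            return self.box
        return self.box[frame]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coordinates[frame]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME_HINTS = {"CL": "Cl", "BR": "Br", "NA": "Na", "MG": "Mg",
                            "ZN": "Zn", "FE": "Fe", "CA": "Ca", "MN": "Mn"}


def _guess_element(name: str, resname: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # Ion/metal residues use two-letter elements; amino acids do not (their
    # "CA" is an alpha carbon, not calcium).
    if resname.strip().upper() in _ELEMENT_FROM_NAME_HINTS and \
            stripped.upper() in _ELEMENT_FROM_NAME_HINTS:
        return _ELEMENT_FROM_NAME_HINTS[stripped.upper()]
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped[0]


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno  # some writers overflow serials; fall back to order
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    resname = line[17:21].strip()  # col 21 tolerates 4-char residue names (TIP3)
    chain = line[21:22].strip() or "A"
    try:
        resid = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad residue number field {line[22:26]!r}") from exc
    icode = line[26:27].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: non-numeric coordinate field") from exc
    occupancy = 1.0
    if len(line) >= 60 and line[54:60].strip():
        try:
            occupancy = float(line[54:60])
        except ValueError:
            occupancy = 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    return dict(serial=serial, name=name, altloc=altloc, resname=resname,
                chain=chain, resid=resid, icode=icode, xyz=(x, y, z),
                occupancy=occupancy, element=element)


def read_structure(
    source: str | Path,
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
) -> ParameterizedSystem:
    """Parse PDB-format content into a system with coordinates attached.

    ``source`` may be a path or the raw text itself.  Waters are flagged by
    residue name; parameters (masses, charges, radii) are left unassigned.
    Alternate locations keep the highest-occupancy conformer (ties: first).
    Only the first MODEL of a multi-model file is read; use
    :func:`read_trajectory` for the frames.
    """
    text = _as_text(source)
    water_set = {w.upper() for w in water_resnames}
    records: list[dict] = []
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec_type = line[:6].strip()
        if rec_type == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec_type == "ENDMDL" and in_model >= 1:
            break
        elif rec_type in {"ATOM", "HETATM"}:
            records.append(_parse_atom_line(line, lineno))
    if not records:
        raise PDBParseError("no ATOM/HETATM records found")

    # Altloc resolution: group by (chain, resid, icode, name).
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec["chain"], rec["resid"], rec["icode"], rec["name"])
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec["occupancy"] > best[key]["occupancy"]:
            best[key] = rec

    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    for i, key in enumerate(order):
        rec = best[key]
        resname = rec["resname"].upper()
        element = rec["element"].strip().capitalize() or _guess_element(rec["name"], resname)
        if len(element) == 1:
            element = element.upper()
        atoms.append(
            AtomRecord(
                serial=i,
                name=rec["name"],
                element=element,
                residue_name=rec["resname"],
                residue_index=rec["resid"],
                chain_id=rec["chain"],
                insertion_code=rec["icode"],
                is_water=resname in water_set,
            )
        )
        coords.append(rec["xyz"])
    return ParameterizedSystem(atoms=atoms, coordinates=np.asarray(coords))


def write_structure(
    system: ParameterizedSystem,
    path: str | Path | None = None,
    coordinates: np.ndarray | None = None,
) -> str:
    """Write a system as fixed-column PDB text; returns the text."""
    coords = coordinates if coordinates is not None else system.coordinates
    if coords is None:
        raise ValueError("no coordinates to write")
    text = _frame_to_pdb(system, np.asarray(coords))
    if path is not None:
        Path(path).write_text(text)
    return text


def _frame_to_pdb(system: ParameterizedSystem, coords: np.ndarray,
                  model: int | None = None) -> str:
    lines = []
    if model is not None:
        lines.append(f"MODEL     {model:4d}")
    for i, a in enumerate(system.atoms):
        record = "HETATM" if a.is_water else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = coords[i]
        lines.append(
            f"{record}{(i + 1) % 100000:5d} {name:<4.4s} {a.residue_name:<4.4s}"
            f"{a.chain_id[:1]:>1s}{a.residue_index:4d}{a.insertion_code[:1]:>1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{a.element:>2.2s}"
        )
    if model is not None:
        lines.append("ENDMDL")
    else:
        lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory_pdb(system: ParameterizedSystem, trajectory: Trajectory,
                         path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(_frame_to_pdb(system, trajectory.coordinates[f], model=f + 1))
        fh.write("END\n")


def write_trajectory_dcd(system: ParameterizedSystem, trajectory: Trajectory,
                         path: str | Path) -> None:
    """Write a trajectory as a CHARMM-style DCD file (via MDAnalysis)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    n = system.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        with DCDWriter(str(path), n) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coordinates[f].astype(np.float32)
                box = trajectory.frame_box(f)
                if box is not None:
                    u.dimensions = [box[0], box[1], box[2], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def read_trajectory(
    path: str | Path,
    system: ParameterizedSystem,
    interval: float,
) -> Trajectory:
    """Read a multi-model PDB, XYZ or DCD trajectory aligned to ``system``.

    ``interval`` is the time between stored frames in ps.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".pdb":
        frames, boxes = _read_multimodel_pdb(p)
    elif suffix in {".dcd", ".xyz"}:
        frames, boxes = _read_with_mdanalysis(p, system.n_atoms)
    else:
        raise ValueError(f"unsupported trajectory format '{suffix}'")
    coords = np.asarray(frames)
    if coords.shape[1] != system.n_atoms:
        raise TrajectoryShapeError(
            f"trajectory has {coords.shape[1]} atoms, system has {system.n_atoms}"
        )
    box = None
    if boxes and any(b is not None for b in boxes):
        box = np.asarray([b if b is not None else (0.0, 0.0, 0.0) for b in boxes])
    return Trajectory(coordinates=coords, frame_interval=interval,
                      box=box, provenance=str(p))


def _read_multimodel_pdb(path: Path) -> tuple[list[np.ndarray], list[None]]:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    saw_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            frames.append(np.asarray(current))
            current = []
        elif rec in {"ATOM", "HETATM"}:
            parsed = _parse_atom_line(line, lineno)
            current.append(parsed["xyz"])
    if current and (not saw_model or not frames):
        frames.append(np.asarray(current))
    if not frames:
        raise PDBParseError("no coordinate frames found")
    return frames, [None] * len(frames)


def _read_with_mdanalysis(path: Path, n_atoms: int) -> tuple[list, list]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except (ValueError, IOError) as exc:
            raise TrajectoryShapeError(
                f"could not load '{path}' with {n_atoms} atoms: {exc}"
            ) from exc
        frames, boxes = [], []
        for ts in u.trajectory:
            if ts.positions.shape[0] != n_atoms:
                raise TrajectoryShapeError(
                    f"trajectory has {ts.positions.shape[0]} atoms, expected {n_atoms}"
                )
            frames.append(ts.positions.astype(float).copy())
            if ts.dimensions is not None and ts.dimensions[:3].any():
                boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
            else:
                boxes.append(None)
    return frames, boxes


def _as_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "\n" in s or s.strip().startswith(("ATOM", "HETATM", "MODEL", "REMARK", "CRYST", "HEADER")):
        return s
    p = Path(s)
    if p.exists():
        return p.read_text()
    return s


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("residue", "atom", "element", "mass", "mm_charge",
                 "parse_charge", "lj_epsilon", "lj_rmin_half",
                 "radius_pb", "radius_sasa")


def read_parameter_table(source: str | Path) -> dict[tuple[str, str], dict]:
    """Read a whitespace/comma-delimited parameter table.

    Expected columns: residue atom element mass mm_charge parse_charge
    lj_epsilon lj_rmin_half radius_pb radius_sasa.  ``residue`` may be ``*``
    as a wildcard matched after exact residue keys.  Lines starting with
    ``#`` are comments.
    """
    text = _as_text(source)
    table: dict[tuple[str, str], dict] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if parts[0].lower() == "residue":
            continue
        if len(parts) != len(TABLE_COLUMNS):
            raise ValueError(
                f"parameter table row has {len(parts)} fields, expected "
                f"{len(TABLE_COLUMNS)}: {raw!r}"
            )
        entry = {"element": parts[2]}
        for col, val in zip(TABLE_COLUMNS[3:], parts[3:]):
            entry[col] = float(val)
        table[(parts[0].upper(), parts[1].upper())] = entry
    return table


def format_parameter_table(table: dict[tuple[str, str], dict]) -> str:
    lines = [" ".join(TABLE_COLUMNS)]
    for (res, atom), entry in table.items():
        vals = " ".join(f"{entry[c]:.6g}" for c in TABLE_COLUMNS[3:])
        lines.append(f"{res} {atom} {entry['element']} {vals}")
    return "\n".join(lines) + "\n"


def assign_parameters(
    system: ParameterizedSystem,
    table: dict[tuple[str, str], dict],
    strict: bool = True,
) -> ParameterizedSystem:
    """Return a copy of ``system`` with per-atom parameters filled in.

    Lookup is by (residue_name, atom_name), falling back to the ``*``
    wildcard residue.  In strict mode any uncovered atom raises
    :class:`MissingParameterError` listing every ``residue:atom`` missed.
    Assignment is idempotent: re-applying the same table is a no-op.
    """
    out = system.copy()
    missing: list[str] = []
    for a in out.atoms:
        key = (a.residue_name.upper(), a.name.upper())
        entry = table.get(key) or table.get(("*", a.name.upper()))
        if entry is None:
            missing.append(f"{a.residue_name}:{a.name}")
            continue
        a.mass = entry["mass"]
        a.mm_charge = entry["mm_charge"]
        a.parse_charge = entry["parse_charge"]
        a.lj_epsilon = entry["lj_epsilon"]
        a.lj_rmin_half = entry["lj_rmin_half"]
        a.radius_pb = entry["radius_pb"]
        a.radius_sasa = entry["radius_sasa"]
        if entry["element"] != "*":
            a.element = entry["element"]
    if missing and strict:
        raise MissingParameterError(
            f"no parameters for {len(missing)} atoms: {', '.join(sorted(set(missing)))}"
        )
    return out


def mainchain_sidechain_split(
    system: ParameterizedSystem, residue_key: tuple[str, int, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Partition one residue's atoms into (mainchain, sidechain) index sets."""
    groups = system.residue_atoms()
    if residue_key not in groups:
        raise SelectionError(f"no residue {residue_key}")
    idx = groups[residue_key]
    main = np.array([i for i in idx if system.atoms[i].name in MAINCHAIN_ATOM_NAMES],
                    dtype=int)
    side = np.array([i for i in idx if system.atoms[i].name not in MAINCHAIN_ATOM_NAMES],
                    dtype=int)
    return main, side


def check_water_neutrality(system: ParameterizedSystem, tol: float = 1e-6) -> None:
    """Raise if any parameterized water molecule carries net MM charge."""
    for key in system.water_residues():
        idx = system.residue_atoms()[key]
        q = sum(system.atoms[i].mm_charge for i in idx)
        if abs(q) > tol:
            raise ValueError(f"water residue {key} has net charge {q:.2e} e")
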