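"""Finite-difference linearized Poisson-Boltzmann solver and SASA terms.

The electrostatic desolvation term is computed on a cubic lattice: the
molecular (solvent-excluded) surface defines the dielectric boundary
(eps_in inside, eps_out in solvent), a Stern layer excludes ions from a
shell around the solute, and the linearized PB equation is solved by
red-black successive over-relaxation with focusing: the coarsest grid spans
the solute plus a margin with Debye-Hückel analytic boundary potentials,
and each finer level takes its boundary from the previous solution.  The
solvation energy is the reaction-field energy: a matched solve with a
homogeneous eps_in dielectric and no salt on the identical final grid
cancels the grid self-energy.

The nonpolar term is a Shrake-Rupley solvent-accessible surface area times
0.00542 kcal/(mol Å²) plus a 0.92 kcal/mol constant (omitted in
per-residue mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .mm import COULOMB_K, KB
from .model_io import ParameterizedSystem

# nonpolar (SASA) coefficients, kcal/mol per Å² and kcal/mol
SASA_SLOPE = 0.00542
SASA_INTERCEPT = 0.92

AVOGADRO = 6.02214076e23


class ConvergenceError(RuntimeError):
    pass


class GridSizingError(ValueError):
    pass


@dataclass
class GridSpec:
    """Lattice geometry for one PB solve level."""

    dimension: int = 129  # points per axis, odd
    spacing: float = 0.5  # Å
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.dimension % 2 == 0:
            raise ValueError("grid dimension must be odd")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        self.center = np.asarray(self.center, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return self.center - 0.5 * (self.dimension - 1) * self.spacing

    @property
    def extent(self) -> float:
        return (self.dimension - 1) * self.spacing


@dataclass
class PBMaps:
    """Face dielectrics, screening and charge maps for one grid."""

    grid: GridSpec
    eps_faces: tuple[np.ndarray, np.ndarray, np.ndarray]  # x, y, z faces
    kappa2: np.ndarray  # eps_out * kappa_D^2 where ions reach, else 0 (Å⁻²)
    charge: np.ndarray  # e per node
    positions: np.ndarray
    charges: np.ndarray
    eps_in: float
    eps_out: float
    kappa_debye: float  # Å⁻¹ in the solvent


@dataclass
class PBResult:
    solvation_energy: float  # kcal/mol (reaction field)
    phi: np.ndarray | None  # final-level potential, kcal/(mol e)
    residual: float
    iterations: int
    grid: GridSpec | None = None


def debye_kappa(ionic_strength: float, eps_out: float = 80.0,
                temperature: float = 300.0) -> float:
    """Inverse Debye length (Å⁻¹) for a 1:1 salt of given molar strength."""
    if ionic_strength <= 0:
        return 0.0
    n = AVOGADRO * ionic_strength * 1e-27  # ions/Å³ per species
    kappa2 = 8.0 * math.pi * COULOMB_K * n / (eps_out * KB * temperature)
    return math.sqrt(kappa2)


def _paint_spheres(mask: np.ndarray, positions: np.ndarray, radii: np.ndarray,
                   origin: np.ndarray, h: float) -> None:
    """Set mask true at lattice points within radii of any sphere center."""
    dim = np.asarray(mask.shape)
    for pos, rad in zip(positions, radii):
        if rad <= 0:
            continue
        lo = np.maximum(0, np.floor((pos - rad - origin) / h).astype(int))
        hi = np.minimum(dim - 1, np.ceil((pos + rad - origin) / h).astype(int))
        if np.any(lo > hi):
            continue
        ax = [origin[d] + h * np.arange(lo[d], hi[d] + 1) - pos[d] for d in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub |= r2 <= rad * rad


def molecular_surface_mask(positions: np.ndarray, radii: np.ndarray,
                           grid: GridSpec, probe: float = 1.4,
                           refine: int = 2) -> np.ndarray:
    """Solvent-excluded interior on a lattice refined ``refine``-fold.

    Probe-accessible centers are lattice points at least ``probe`` outside
    every atom; the solvent region is everything within ``probe`` of an
    accessible center (a morphological closing of the van der Waals volume);
    the interior is its complement, unioned with the vdW volume itself.
    Returned lattice has ``refine*(dimension-1)+1`` points per axis.
    """
    h = grid.spacing / refine
    n = refine * (grid.dimension - 1) + 1
    origin = grid.origin
    shape = (n, n, n)
    vdw = np.zeros(shape, dtype=bool)
    _paint_spheres(vdw, positions, radii, origin, h)
    inflated = np.zeros(shape, dtype=bool)
    _paint_spheres(inflated, positions, radii + probe, origin, h)
    # distance from each point to the nearest probe-accessible point
    dist = ndimage.distance_transform_edt(inflated, sampling=h)
    interior = dist > probe
    interior |= vdw
    return interior


def build_maps(
    system: ParameterizedSystem,
    indices: np.ndarray,
    grid: GridSpec,
    eps_in: float = 2.0,
    eps_out: float = 80.0,
    ionic_strength: float = 0.145,
    stern: float = 2.0,
    probe: float = 1.4,
    temperature: float = 300.0,
    positions: np.ndarray | None = None,
    reference: bool = False,
) -> PBMaps:
    """Dielectric, ion-accessibility and charge maps for one solute subset.

    ``reference=True`` builds the matched homogeneous problem (eps_in
    everywhere, no salt) used to cancel the grid self-energy.  PARSE
    charges and PB radii must be assigned.
    """
    idx = np.asarray(indices, dtype=int)
    pos = (positions if positions is not None else system.coordinates)[idx]
    q = system.parse_charges()[idx]
    radii = np.array([system.atoms[i].radius_pb for i in idx])
    half = 0.5 * grid.extent
    if np.any(np.abs(pos - grid.center) > half - grid.spacing):
        raise GridSizingError("solute extends beyond the grid")

    d = grid.dimension
    if reference:
        eps_x = np.full((d - 1, d, d), eps_in)
        eps_y = np.full((d, d - 1, d), eps_in)
        eps_z = np.full((d, d, d - 1), eps_in)
        kappa2 = np.zeros((d, d, d))
        kappa_d = 0.0
    else:
        fine = molecular_surface_mask(pos, radii, grid, probe=probe, refine=2)
        eps_fine = np.where(fine, eps_in, eps_out)
        nodes = eps_fine[::2, ::2, ::2]
        # face dielectric: series (harmonic) combination of the two edge
        # halves, each sampled at node and midpoint -> weights (1, 2, 1)
        inv = 1.0 / eps_fine
        eps_x = 4.0 / (inv[0:-2:2, ::2, ::2] + 2 * inv[1::2, ::2, ::2]
                       + inv[2::2, ::2, ::2])
        eps_y = 4.0 / (inv[::2, 0:-2:2, ::2] + 2 * inv[::2, 1::2, ::2]
                       + inv[::2, 2::2, ::2])
        eps_z = 4.0 / (inv[::2, ::2, 0:-2:2] + 2 * inv[::2, ::2, 1::2]
                       + inv[::2, ::2, 2::2])
        kappa_d = debye_kappa(ionic_strength, eps_out, temperature)
        kappa2 = np.zeros((d, d, d))
        if kappa_d > 0:
            stern_mask = np.zeros((d, d, d), dtype=bool)
            _paint_spheres(stern_mask, pos, radii + stern, grid.origin,
                           grid.spacing)
            ion_ok = ~(stern_mask | (nodes == eps_in))
            kappa2[ion_ok] = eps_out * kappa_d**2

    charge = np.zeros((d, d, d))
    frac = (pos - grid.origin) / grid.spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    for corner in np.ndindex(2, 2, 2):
        w = np.prod(np.where(np.array(corner), t, 1.0 - t), axis=1)
        np.add.at(charge, tuple((base + corner).T), q * w)
    return PBMaps(grid=grid, eps_faces=(eps_x, eps_y, eps_z), kappa2=kappa2,
                  charge=charge, positions=pos, charges=q,
                  eps_in=eps_in, eps_out=eps_out, kappa_debye=kappa_d)


def analytic_boundary(maps: PBMaps) -> np.ndarray:
    """Debye-Hückel (or Coulomb) boundary potential on the grid faces.

    Fills only the 6 boundary faces of a (d,d,d) array; interior stays 0.
    For the homogeneous reference problem the screened constant is eps_in
    with no salt.
    """
    grid = maps.grid
    d = grid.dimension
    phi = np.zeros((d, d, d))
    eps = maps.eps_in if maps.kappa_debye == 0 and np.all(
        maps.eps_faces[0] == maps.eps_in) else maps.eps_out
    coords = grid.origin[None, :] + grid.spacing * np.indices((d, d, d)).reshape(3, -1).T
    boundary = np.zeros((d, d, d), dtype=bool)
    for axis in range(3):
        sl: list = [slice(None)] * 3
        sl[axis] = 0
        boundary[tuple(sl)] = True
        sl[axis] = d - 1
        boundary[tuple(sl)] = True
    bpts = coords[boundary.ravel()]
    vals = np.zeros(len(bpts))
    for p, q in zip(maps.positions, maps.charges):
        if q == 0.0:
            continue
        r = np.linalg.norm(bpts - p, axis=1)
        r = np.maximum(r, 1e-6)
        vals += COULOMB_K * q * np.exp(-maps.kappa_debye * r) / (eps * r)
    phi[boundary] = vals
    return phi


def solve_pb(
    maps: PBMaps,
    tolerance: float = 1e-6,
    max_iter: int = 20000,
    omega: float = 1.9,
    boundary: np.ndarray | None = None,
) -> PBResult:
    """Red-black SOR solution of the linearized PB equation on one grid.

    ``boundary`` supplies Dirichlet values on the outer faces (defaults to
    the Debye-Hückel analytic potential).  Raises
    :class:`ConvergenceError` if the relative residual does not reach
    ``tolerance`` within ``max_iter`` sweeps.
    """
    grid = maps.grid
    d = grid.dimension
    h = grid.spacing
    eps_x, eps_y, eps_z = maps.eps_faces
    phi = analytic_boundary(maps) if boundary is None else boundary.copy()

    src = 4.0 * math.pi * COULOMB_K * maps.charge / h  #: (Σ eps) φ units
    diag = np.zeros((d, d, d))
    diag[:-1] += eps_x
    diag[1:] += eps_x
    diag[:, :-1] += eps_y
    diag[:, 1:] += eps_y
    diag[:, :, :-1] += eps_z
    diag[:, :, 1:] += eps_z
    diag += maps.kappa2 * h * h

    ii, jj, kk = np.indices((d, d, d))
    parity = (ii + jj + kk) % 2
    interior = np.zeros((d, d, d), dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    masks = [interior & (parity == 0), interior & (parity == 1)]

    def neighbor_sum(p: np.ndarray) -> np.ndarray:
        out = np.zeros_like(p)
        out[1:] += eps_x * p[:-1]
        out[:-1] += eps_x * p[1:]
        out[:, 1:] += eps_y * p[:, :-1]
        out[:, :-1] += eps_y * p[:, 1:]
        out[:, :, 1:] += eps_z * p[:, :, :-1]
        out[:, :, :-1] += eps_z * p[:, :, 1:]
        return out

    b_norm = np.linalg.norm(src[interior]) + 1e-300
    residual = np.inf
    it = 0
    while it < max_iter:
        for m in masks:
            nb = neighbor_sum(phi)
            phi[m] += omega * ((nb[m] + src[m]) / diag[m] - phi[m])
        it += 1
        if it % 10 == 0 or it == max_iter:
            nb = neighbor_sum(phi)
            res = (diag * phi - nb - src)[interior]
            residual = np.linalg.norm(res) / max(b_norm,
                                                 np.linalg.norm((diag * phi)[interior]))
            if residual < tolerance:
                break
    if residual >= tolerance:
        raise ConvergenceError(
            f"PB solver did not converge: residual {residual:.2e} after {it} sweeps")
    energy = 0.5 * float(np.sum(_interp_trilinear(phi, maps) * maps.charges))
    return PBResult(solvation_energy=energy, phi=phi, residual=residual,
                    iterations=it, grid=grid)


def _interp_trilinear(phi: np.ndarray, maps: PBMaps) -> np.ndarray:
    grid = maps.grid
    frac = (maps.positions - grid.origin) / grid.spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    out = np.zeros(len(maps.positions))
    for corner in np.ndindex(2, 2, 2):
        w = np.prod(np.where(np.array(corner), t, 1.0 - t), axis=1)
        out += w * phi[tuple((base + corner).T)]
    return out


@dataclass
class PBSettings:
    """Grid and physics settings for a focused PB solvation calculation."""

    dimension: int = 129
    levels: int = 3
    margin: float = 20.0  # Å added around the solute at the coarsest level
    final_spacing: float = 0.5  # Å target at the finest level
    eps_in: float = 2.0
    eps_out: float = 80.0
    ionic_strength: float = 0.145  # M
    stern: float = 2.0  # Å
    probe: float = 1.4  # Å
    temperature: float = 300.0  # K
    tolerance: float = 1e-6
    max_iter: int = 20000
    omega: float = 1.9


def focusing_grids(positions: np.ndarray, radii: np.ndarray,
                   settings: PBSettings,
                   center: np.ndarray | None = None) -> list[GridSpec]:
    """Geometrically nested grids from solute+margin down to the target spacing."""
    pos = np.asarray(positions, dtype=float)
    if center is None:
        center = 0.5 * (pos.min(axis=0) + pos.max(axis=0))
    rmax = float(radii.max()) if len(radii) else 1.5
    need = 2 * (np.max(np.abs(pos - center)) + rmax + settings.margin)
    h0 = max(need / (settings.dimension - 1),
             2 * (np.max(np.abs(pos - center)) + rmax) / (settings.dimension - 5))
    hf = min(settings.final_spacing, h0)
    # finest grid must still contain the solute with a 2-cell margin
    dmax = float(np.max(np.abs(pos - center))) + rmax
    hf_min = 2 * dmax / (settings.dimension - 5)
    hf = max(hf, hf_min)
    n_levels = max(1, settings.levels)
    if h0 <= hf:
        return [GridSpec(settings.dimension, h0, center)]
    ratios = np.geomspace(h0, hf, n_levels)
    return [GridSpec(settings.dimension, float(h), center) for h in ratios]


def _focus_boundary(phi_prev: np.ndarray, prev: GridSpec, new: GridSpec) -> np.ndarray:
    """Boundary values for a finer grid interpolated from the coarser solve."""
    d = new.dimension
    phi = np.zeros((d, d, d))
    boundary = np.zeros((d, d, d), dtype=bool)
    for axis in range(3):
        sl: list = [slice(None)] * 3
        sl[axis] = 0
        boundary[tuple(sl)] = True
        sl[axis] = d - 1
        boundary[tuple(sl)] = True
    idx = np.argwhere(boundary)
    pts = new.origin + new.spacing * idx
    frac = (pts - prev.origin) / prev.spacing
    frac = np.clip(frac, 0, prev.dimension - 1 - 1e-9)
    vals = ndimage.map_coordinates(phi_prev, frac.T, order=1)
    phi[boundary] = vals
    return phi


def pb_solvation_energy(
    system: ParameterizedSystem,
    indices: np.ndarray,
    settings: PBSettings | None = None,
    positions: np.ndarray | None = None,
    grids: list[GridSpec] | None = None,
) -> PBResult:
    """Reaction-field solvation energy of one solute subset with focusing.

    Runs the focusing ladder for the heterogeneous (solvated) problem, then
    a matched homogeneous eps_in / no-salt solve on the identical finest
    grid; the difference of ½Σqφ between the two cancels the grid
    self-energy.
    """
    settings = settings or PBSettings()
    idx = np.asarray(indices, dtype=int)
    pos = (positions if positions is not None else system.coordinates)[idx]
    radii = np.array([system.atoms[i].radius_pb for i in idx])
    if grids is None:
        grids = focusing_grids(pos, radii, settings)
    phi_prev: np.ndarray | None = None
    prev_grid: GridSpec | None = None
    result: PBResult | None = None
    iterations = 0
    for grid in grids:
        maps = build_maps(system, idx, grid, eps_in=settings.eps_in,
                          eps_out=settings.eps_out,
                          ionic_strength=settings.ionic_strength,
                          stern=settings.stern, probe=settings.probe,
                          temperature=settings.temperature,
                          positions=positions)
        boundary = (None if phi_prev is None
                    else _focus_boundary(phi_prev, prev_grid, grid))
        result = solve_pb(maps, tolerance=settings.tolerance,
                          max_iter=settings.max_iter, omega=settings.omega,
                          boundary=boundary)
        iterations += result.iterations
        phi_prev, prev_grid = result.phi, grid
    # matched homogeneous reference on the finest grid
    ref_maps = build_maps(system, idx, grids[-1], eps_in=settings.eps_in,
                          eps_out=settings.eps_out, ionic_strength=0.0,
                          stern=settings.stern, probe=settings.probe,
                          positions=positions, reference=True)
    ref = solve_pb(ref_maps, tolerance=settings.tolerance,
                   max_iter=settings.max_iter, omega=settings.omega)
    energy = result.solvation_energy - ref.solvation_energy
    return PBResult(solvation_energy=energy, phi=result.phi,
                    residual=max(result.residual, ref.residual),
                    iterations=iterations + ref.iterations, grid=grids[-1])


def delta_g_pb(
    system: ParameterizedSystem,
    complex_idx: np.ndarray,
    protein_idx: np.ndarray,
    peptide_idx: np.ndarray,
    frames: np.ndarray,
    settings: PBSettings | None = None,
) -> np.ndarray:
    """PB desolvation penalty per frame.

    ΔG_PB = G_pb(complex) − G_pb(protein) − G_pb(peptide), with all three
    solves on identical grid geometry (the complex's focusing ladder) for
    each frame.
    """
    settings = settings or PBSettings()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    out = np.empty(len(frames))
    radii = np.array([a.radius_pb for a in system.atoms])
    for f, frame in enumerate(frames):
        cpos = frame[np.asarray(complex_idx, dtype=int)]
        grids = focusing_grids(cpos, radii[np.asarray(complex_idx, dtype=int)],
                               settings)
        g_c = pb_solvation_energy(system, complex_idx, settings,
                                  positions=frame, grids=grids).solvation_energy
        g_p = pb_solvation_energy(system, protein_idx, settings,
                                  positions=frame, grids=grids).solvation_energy
        g_l = pb_solvation_energy(system, peptide_idx, settings,
                                  positions=frame, grids=grids).solvation_energy
        out[f] = g_c - g_p - g_l
    return out


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + math.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(
    system: ParameterizedSystem,
    indices: np.ndarray,
    frame: np.ndarray | None = None,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-atom Å² aligned to ``indices``, total).  Atoms with zero
    SASA radius are excluded with a warning and contribute zero area (and
    do not bury their neighbours).
    """
    idx = np.asarray(indices, dtype=int)
    coords = (frame if frame is not None else system.coordinates)[idx]
    radii = np.array([system.atoms[i].radius_sasa for i in idx])
    live = radii > 0
    if not np.all(live):
        warnings.warn(f"{int((~live).sum())} zero-radius atoms excluded from SASA")
    unit = _sphere_points(n_sphere_points)
    areas = np.zeros(idx.size)
    live_idx = np.flatnonzero(live)
    if live_idx.size == 0:
        return areas, 0.0
    pos = coords[live_idx]
    rad = radii[live_idx] + probe
    tree = cKDTree(pos)
    pairs = tree.query_ball_point(pos, r=2 * rad.max())
    for a, local in enumerate(pairs):
        neighbors = [b for b in local if b != a
                     and np.linalg.norm(pos[b] - pos[a]) < rad[a] + rad[b]]
        pts = pos[a] + rad[a] * unit
        exposed = np.ones(len(pts), dtype=bool)
        for b in neighbors:
            d2 = np.sum((pts - pos[b]) ** 2, axis=1)
            exposed &= d2 > rad[b] ** 2
        areas[live_idx[a]] = 4.0 * math.pi * rad[a] ** 2 * exposed.mean()
    return areas, float(areas.sum())


def delta_g_sa(delta_sasa: float, include_constant: bool = True) -> float:
    """Nonpolar desolvation term, linear in the SASA change upon binding."""
    value = SASA_SLOPE * delta_sasa
    if include_constant:
        value += SASA_INTERCEPT
    return value
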