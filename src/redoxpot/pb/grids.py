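"""Grid data structures: dielectric maps, charge grids, potentials.

Dielectric values live on edge midpoints of the node lattice (one array
per axis).  Region assignment uses the union of atomic spheres with
precedence redox-site > protein > solvent; values across a region
boundary are harmonically averaged from sub-samples along each edge,
which is what gives the solver its near-second-order behaviour on the
Born benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridSpec",
    "PBParams",
    "PBSystem",
    "DielectricMap",
    "ChargeGrid",
    "PotentialMap",
    "GeometryError",
    "grid_from_atoms",
    "build_dielectric_map",
    "spread_charges",
    "write_opendx",
]

#: Number of sub-samples per edge used for harmonic dielectric averaging.
EDGE_SUBSAMPLES = 3

#: Minimum per-axis node count recommended for production solves.
PRODUCTION_MIN_DIMS = 33


class GeometryError(ValueError):
    """Atom falls outside the grid box (or inside its boundary layer)."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned cubic-spacing node lattice.

    Attributes
    ----------
    origin : ndarray, shape (3,)
        Coordinates of node (0, 0, 0) in Angstrom.
    spacing : float
        Node spacing in Angstrom (identical on all axes).
    dims : tuple of int
        Number of nodes per axis.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def shape(self):
        return self.dims

    @property
    def extent(self) -> np.ndarray:
        return (np.asarray(self.dims) - 1) * self.spacing

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.extent

    def axes(self):
        """Per-axis node coordinate vectors."""
        return tuple(self.origin[i] + self.spacing * np.arange(self.dims[i])
                     for i in range(3))

    def contains(self, coords: np.ndarray, margin: float = 0.0) -> np.ndarray:
        coords = np.atleast_2d(coords)
        lo = self.origin + margin
        hi = self.upper - margin
        return np.all((coords >= lo) & (coords <= hi), axis=1)

    def is_production(self) -> bool:
        return all(d >= PRODUCTION_MIN_DIMS for d in self.dims)


@dataclass(frozen=True)
class PBParams:
    """Parameters of a Poisson-Boltzmann run.

    The three dielectric regions follow the redox-cycle convention:
    ``eps_core`` inside redox-site atoms, ``eps_protein`` inside all
    other solute atoms, ``eps_solvent`` elsewhere.
    """

    eps_core: float = 1.0
    eps_protein: float = 4.0
    eps_solvent: float = 78.0
    ionic_strength: float = 0.0
    temperature: float = 298.15
    spacing_fine: float = 0.4
    spacing_coarse: float = 1.0
    padding: float = 20.0
    fine_margin: float = 5.0
    tol: float = 1e-6
    max_iter: int = 20000

    def __post_init__(self):
        for name in ("eps_core", "eps_protein", "eps_solvent"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def replace(self, **kw) -> "PBParams":
        return replace(self, **kw)


@dataclass
class PBSystem:
    """Point-charge view of a parameterized system for the PB engine.

    Attributes
    ----------
    coords : ndarray, shape (n, 3)
    charges : ndarray, shape (n,)
        Partial charges in e.
    radii : ndarray, shape (n,)
        Dielectric-region radii in Angstrom.
    site_mask : ndarray of bool, shape (n,)
        True for redox-site atoms (the ``eps_core`` region).
    """

    coords: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    site_mask: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.site_mask = np.asarray(self.site_mask, dtype=bool)
        n = len(self.coords)
        if not (len(self.charges) == len(self.radii) == len(self.site_mask) == n):
            raise ValueError("inconsistent PBSystem array lengths")
        if np.any(self.radii < 0):
            raise ValueError("radii must be >= 0")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def subset(self, mask) -> "PBSystem":
        mask = np.asarray(mask)
        return PBSystem(self.coords[mask], self.charges[mask],
                        self.radii[mask], self.site_mask[mask])

    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class DielectricMap:
    """Edge-centered dielectric values.

    ``eps[axis]`` holds the permittivity on edges along ``axis``; the
    array along axis ``a`` is one shorter than the node grid on that
    axis.  ``kappa_sq`` is the (node-centered) screening term, zero
    unless the ionic strength is nonzero.
    """

    grid: GridSpec
    eps: tuple  # (eps_x, eps_y, eps_z)
    kappa_sq: np.ndarray | None = None
    uniform_value: float | None = None  # set when the map is spatially uniform

    @property
    def is_uniform(self) -> bool:
        return self.uniform_value is not None


@dataclass
class ChargeGrid:
    """Node charges in e, produced by trilinear spreading."""

    grid: GridSpec
    values: np.ndarray

    def total_charge(self) -> float:
        return float(self.values.sum())


@dataclass
class PotentialMap:
    """Node potentials in kcal/(mol*e)."""

    grid: GridSpec
    values: np.ndarray
    meta: dict = field(default_factory=dict)


def grid_from_atoms(coords, radii, spacing, margin=5.0, align_origin=None):
    """Build a :class:`GridSpec` covering all atom spheres plus ``margin``.

    Parameters
    ----------
    align_origin : ndarray, optional
        If given, the origin is snapped onto the lattice defined by this
        point and ``spacing`` so that nested grids share node positions.
    """
    coords = np.atleast_2d(coords)
    radii = np.asarray(radii, dtype=float)
    lo = (coords - radii[:, None]).min(axis=0) - margin
    hi = (coords + radii[:, None]).max(axis=0) + margin
    if align_origin is not None:
        lo = align_origin + np.floor((lo - align_origin) / spacing) * spacing
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    return GridSpec(origin=lo, spacing=spacing, dims=tuple(dims))


def _paint_inside(points_origin, spacing, shape, coords, radii, out):
    """Mark lattice points inside any of the given spheres (in place).

    The lattice is ``points_origin + spacing * index``.  Atoms are
    visited one by one, each touching only its local bounding box.
    """
    if len(coords) == 0:
        return
    lo_idx = np.ceil((coords - radii[:, None] - points_origin) / spacing).astype(int)
    hi_idx = np.floor((coords + radii[:, None] - points_origin) / spacing).astype(int)
    np.clip(lo_idx, 0, np.asarray(shape) - 1, out=lo_idx)
    np.clip(hi_idx, -1, np.asarray(shape) - 1, out=hi_idx)
    for a in range(len(coords)):
        if radii[a] <= 0:
            continue
        i0, j0, k0 = lo_idx[a]
        i1, j1, k1 = hi_idx[a] + 1
        if i1 <= i0 or j1 <= j0 or k1 <= k0:
            continue
        x = points_origin[0] + spacing * np.arange(i0, i1) - coords[a, 0]
        y = points_origin[1] + spacing * np.arange(j0, j1) - coords[a, 1]
        z = points_origin[2] + spacing * np.arange(k0, k1) - coords[a, 2]
        d2 = (x[:, None, None] ** 2 + y[None, :, None] ** 2
              + z[None, None, :] ** 2)
        out[i0:i1, j0:j1, k0:k1] |= d2 < radii[a] ** 2


def build_dielectric_map(system: PBSystem, grid: GridSpec, params: PBParams,
                         uniform: float | None = None) -> DielectricMap:
    """Assign edge-centered dielectrics for the three-region model.

    A sample point inside any redox-site atom sphere gets ``eps_core``;
    otherwise inside any other solute sphere, ``eps_protein``; otherwise
    ``eps_solvent``.  Each edge value is the harmonic mean of
    ``EDGE_SUBSAMPLES`` point samples along the edge.

    With ``uniform`` set, every edge gets that single value (the vacuum
    reference map) and no geometry is examined.

    Raises
    ------
    GeometryError
        If any atom sphere pokes out of the grid box.
    """
    h = grid.spacing
    if uniform is None:
        inside = grid.contains(system.coords - system.radii[:, None]) \
            & grid.contains(system.coords + system.radii[:, None])
        if not np.all(inside):
            bad = np.where(~inside)[0]
            raise GeometryError(
                f"{len(bad)} atom(s) outside grid box (first index {bad[0]})")
        if params.eps_core == params.eps_protein == params.eps_solvent \
                and params.ionic_strength == 0:
            # spatially uniform by construction; use the exact direct path
            uniform = params.eps_solvent

    eps_arrays = []
    kappa_sq = None
    for axis in range(3):
        shape = list(grid.dims)
        shape[axis] -= 1
        shape = tuple(shape)
        if uniform is not None:
            eps_arrays.append(np.full(shape, float(uniform)))
            continue
        inv_sum = np.zeros(shape)
        site = system.coords[system.site_mask]
        site_r = system.radii[system.site_mask]
        prot = system.coords[~system.site_mask]
        prot_r = system.radii[~system.site_mask]
        for s in range(EDGE_SUBSAMPLES):
            frac = (2 * s + 1) / (2 * EDGE_SUBSAMPLES)
            offset = np.zeros(3)
            offset[axis] = frac * h
            origin = grid.origin + offset
            in_site = np.zeros(shape, dtype=bool)
            in_prot = np.zeros(shape, dtype=bool)
            _paint_inside(origin, h, shape, site, site_r, in_site)
            _paint_inside(origin, h, shape, prot, prot_r, in_prot)
            eps = np.full(shape, params.eps_solvent)
            eps[in_prot] = params.eps_protein
            eps[in_site] = params.eps_core
            inv_sum += 1.0 / eps
        eps_arrays.append(EDGE_SUBSAMPLES / inv_sum)

    if uniform is None and params.ionic_strength > 0:
        from ..constants import kappa_bar_squared
        in_solute = np.zeros(grid.dims, dtype=bool)
        _paint_inside(grid.origin, h, grid.dims, system.coords,
                      system.radii, in_solute)
        kappa_sq = np.where(in_solute, 0.0,
                            kappa_bar_squared(params.ionic_strength,
                                              params.temperature))

    return DielectricMap(grid=grid, eps=tuple(eps_arrays), kappa_sq=kappa_sq,
                         uniform_value=uniform)


def spread_charges(system: PBSystem, grid: GridSpec) -> ChargeGrid:
    """Distribute atomic charges onto the 8 surrounding nodes (trilinear).

    Conserves total charge to machine precision.  Atoms whose charges
    would touch the outermost node layer raise :class:`GeometryError`
    because those nodes carry Dirichlet boundary values.
    """
    h = grid.spacing
    coords = system.coords
    q = system.charges
    rel = (coords - grid.origin) / h
    base = np.floor(rel).astype(int)
    frac = rel - base
    dims = np.asarray(grid.dims)
    # keep charged atoms off the boundary layer
    charged = q != 0
    if np.any((base[charged] < 1) | (base[charged] + 1 > dims - 2)):
        raise GeometryError("charged atom in or beyond the grid boundary layer")
    values = np.zeros(grid.dims)
    for dx in (0, 1):
        wx = np.where(dx, frac[:, 0], 1 - frac[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, frac[:, 1], 1 - frac[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, frac[:, 2], 1 - frac[:, 2])
                np.add.at(values,
                          (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          q * wx * wy * wz)
    return ChargeGrid(grid=grid, values=values)


def write_opendx(path, grid: GridSpec, values: np.ndarray, name="scalar field"):
    """Write a scalar node field in OpenDX regular-grid format."""
    values = np.asarray(values)
    if tuple(values.shape) != tuple(grid.dims):
        raise ValueError("field shape does not match grid dims")
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"# {name}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6f} 0.0 0.0\n")
        fh.write(f"delta 0.0 {grid.spacing:.6f} 0.0\n")
        fh.write(f"delta 0.0 0.0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{values.size} data follows\n")
        flat = values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{name}" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
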