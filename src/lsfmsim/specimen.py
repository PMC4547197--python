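"""Virtual specimens: the annotated fluorescent volume grid and its generators.

The specimen is a dense axis-aligned voxel grid storing, per voxel, a dye
concentration ``N`` (molecules·cm⁻³) and an integer index into a fluorophore
table (−1 marks a non-fluorescent voxel).  World coordinates are µm in a
right-handed frame: the detection axis is +z, the light sheet propagates
along +x and its plane spans x–y.

Generators: a homogeneous cube (brightness-validation phantom), solid
voxelization of sphere/cylinder primitives (center-in-solid test), and a
seeded synthetic "neuron" builder (soma spheres plus random-walk neurites)
standing in for mesh-derived tissue blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .spectral import Fluorophore

__all__ = [
    "AnnotatedFluorescentVolumeGrid",
    "FluorophoreTable",
    "Sphere",
    "Cylinder",
    "make_homogeneous_cube",
    "voxelize_primitives",
    "make_synthetic_neurons",
    "sample_density",
    "sample_dye",
    "save_grid",
    "load_grid",
    "grid_from_tiff",
]


@dataclass
class FluorophoreTable:
    """Ordered list of dyes referenced by voxel dye indices."""

    entries: list[Fluorophore] = field(default_factory=list)

    def __post_init__(self):
        names = [f.name for f in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("fluorophore names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> Fluorophore:
        return self.entries[i]

    def index_of(self, name: str) -> int:
        for i, f in enumerate(self.entries):
            if f.name == name:
                return i
        raise KeyError(name)


@dataclass
class AnnotatedFluorescentVolumeGrid:
    """Dense voxel grid of dye concentration and dye identity.

    ``density``/``dye_index`` are indexed ``[ix, iy, iz]``.  Voxel ``i`` along
    an axis covers the half-open world interval
    ``[origin + i·vs, origin + (i+1)·vs)``; its center is at
    ``origin + (i+0.5)·vs``.
    """

    dims: tuple[int, int, int]
    voxel_size_um: float
    origin_um: np.ndarray  # world position of the minimum corner, shape (3,)
    density: np.ndarray  # molecules/cm^3, shape dims
    dye_index: np.ndarray  # int, -1 = non-fluorescent, shape dims
    sigma_s_elastic_cm: float = 0.0  # elastic scattering coeff inside specimen

    def __post_init__(self):
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.dye_index = np.asarray(self.dye_index, dtype=np.int32)
        if self.density.shape != tuple(self.dims) or self.dye_index.shape != tuple(self.dims):
            raise ValueError("density/dye_index shapes must equal dims")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if np.any((self.density > 0) & (self.dye_index < 0)):
            raise ValueError("fluorescent voxels (density > 0) need a dye index")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def size_um(self) -> np.ndarray:
        return np.asarray(self.dims, dtype=float) * self.voxel_size_um

    @property
    def max_corner_um(self) -> np.ndarray:
        return self.origin_um + self.size_um

    def world_bounds(self, pad_half_voxel: bool = True):
        """(lo, hi) world AABB; padded by vs/2 to cover the interpolation taper."""
        pad = 0.5 * self.voxel_size_um if pad_half_voxel else 0.0
        return self.origin_um - pad, self.max_corner_um + pad

    def voxel_centers(self):
        """Per-axis arrays of voxel-center coordinates (x, y, z)."""
        vs = self.voxel_size_um
        return tuple(
            self.origin_um[a] + (np.arange(self.dims[a]) + 0.5) * vs
            for a in range(3)
        )


def sample_density(grid: AnnotatedFluorescentVolumeGrid, points) -> np.ndarray:
    """Trilinear interpolation of voxel-center densities at world points (µm).

    Values taper linearly to 0 over the half-voxel beyond the boundary voxel
    centers (zero ghost cells), which conserves the volume integral of the
    field; points outside the padded bounds read 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = ((pts - grid.origin_um) / grid.voxel_size_um - 0.5).T
    return map_coordinates(
        grid.density, coords, order=1, mode="grid-constant", cval=0.0
    )


def sample_dye(grid: AnnotatedFluorescentVolumeGrid, points) -> np.ndarray:
    """Nearest-voxel dye index at world points; −1 outside the grid.

    Points in the half-voxel interpolation skirt (where the density tapers
    to zero) clamp to the boundary voxel, so tapered density always carries
    the dye identity of the voxel it spills from.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    g = (pts - grid.origin_um) / grid.voxel_size_um
    idx = np.floor(g).astype(np.int64)
    dims = np.asarray(grid.dims)
    inside = np.all((g >= -0.5) & (g < dims + 0.5), axis=1)
    idx = np.clip(idx, 0, dims - 1)
    out = np.full(len(pts), -1, dtype=np.int32)
    if inside.any():
        ii = idx[inside]
        out[inside] = grid.dye_index[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def make_homogeneous_cube(
    side_um: float,
    density: float,
    dye_index: int = 0,
    voxel_size_um: float = 0.1,
    sigma_s_elastic_cm: float = 0.0,
) -> AnnotatedFluorescentVolumeGrid:
    """Homogeneous fluorescent cube centered at the world origin.

    The brightness-validation phantom: every voxel carries the same
    concentration and dye index.  ``voxel_size_um`` must divide ``side_um``.
    """
    if side_um <= 0:
        raise ValueError("side must be positive")
    n = side_um / voxel_size_um
    if abs(n - round(n)) > 1e-9:
        raise ValueError("voxel_size must divide the cube side exactly")
    n = int(round(n))
    dims = (n, n, n)
    dens = np.full(dims, float(density))
    dye = np.full(dims, dye_index if density > 0 else -1, dtype=np.int32)
    if density == 0:
        dens[:] = 0.0
    origin = np.full(3, -side_um / 2.0)
    return AnnotatedFluorescentVolumeGrid(
        dims, voxel_size_um, origin, dens, dye, sigma_s_elastic_cm
    )


@dataclass(frozen=True)
class Sphere:
    center_um: tuple[float, float, float]
    radius_um: float
    density: float
    dye_index: int

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = np.sum((pts - np.asarray(self.center_um)) ** 2, axis=-1)
        return d2 <= self.radius_um**2


@dataclass(frozen=True)
class Cylinder:
    """Capped cylinder from p0 to p1 with constant radius."""

    p0_um: tuple[float, float, float]
    p1_um: tuple[float, float, float]
    radius_um: float
    density: float
    dye_index: int

    def contains(self, pts: np.ndarray) -> np.ndarray:
        a = np.asarray(self.p0_um, dtype=float)
        b = np.asarray(self.p1_um, dtype=float)
        ab = b - a
        L2 = float(ab @ ab)
        if L2 == 0:
            d2 = np.sum((pts - a) ** 2, axis=-1)
            return d2 <= self.radius_um**2
        t = ((pts - a) @ ab) / L2
        proj = a + t[..., None] * ab
        d2 = np.sum((pts - proj) ** 2, axis=-1)
        # flat caps: axial coordinate must lie between the end planes
        return (t >= 0.0) & (t <= 1.0) & (d2 <= self.radius_um**2)


def _shape_bounds(shape):
    """World AABB of a primitive (for voxelization windowing)."""
    r = shape.radius_um
    if isinstance(shape, Sphere):
        c = np.asarray(shape.center_um, dtype=float)
        return c - r, c + r
    a = np.asarray(shape.p0_um, dtype=float)
    b = np.asarray(shape.p1_um, dtype=float)
    return np.minimum(a, b) - r, np.maximum(a, b) + r


def voxelize_primitives(
    shapes,
    voxel_size_um: float,
    bounds_lo_um,
    bounds_hi_um,
    sigma_s_elastic_cm: float = 0.0,
) -> AnnotatedFluorescentVolumeGrid:
    """Solid voxelization of sphere/cylinder primitives by voxel-center test.

    A voxel is fluorescent iff its center lies inside at least one shape.
    Overlaps: densities sum, the last-listed shape wins the dye index.  An
    empty shape list yields an all-empty (dye −1) grid.
    """
    lo = np.asarray(bounds_lo_um, dtype=float)
    hi = np.asarray(bounds_hi_um, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("bounds_hi must exceed bounds_lo on every axis")
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / voxel_size_um - 1e-9)) for a in range(3))
    dens = np.zeros(dims)
    dye = np.full(dims, -1, dtype=np.int32)
    axes = [lo[a] + (np.arange(dims[a]) + 0.5) * voxel_size_um for a in range(3)]
    for shape in shapes:
        if shape.radius_um <= 0:
            raise ValueError("primitive radius must be positive")
        # restrict the center-in-solid test to the shape's bounding box
        s_lo, s_hi = _shape_bounds(shape)
        sl = []
        for a in range(3):
            i0 = int(np.searchsorted(axes[a], s_lo[a] - 1e-9))
            i1 = int(np.searchsorted(axes[a], s_hi[a] + 1e-9))
            sl.append(slice(i0, i1))
        if any(s.start >= s.stop for s in sl):
            continue
        X, Y, Z = np.meshgrid(
            axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
        )
        centers = np.stack([X, Y, Z], axis=-1)
        mask = shape.contains(centers)
        dens[sl[0], sl[1], sl[2]][mask] += shape.density
        dye[sl[0], sl[1], sl[2]][mask] = shape.dye_index
    return AnnotatedFluorescentVolumeGrid(
        dims, voxel_size_um, lo, dens, dye, sigma_s_elastic_cm
    )


def make_synthetic_neurons(
    n_cells: int,
    seed: int,
    bounds_lo_um,
    bounds_hi_um,
    dye_indices=None,
    density: float = 1.0e18,
    voxel_size_um: float = 0.5,
    sigma_s_elastic_cm: float = 0.0,
) -> AnnotatedFluorescentVolumeGrid:
    """Seeded primitive-based stand-in for a fluorescent-tagged tissue block.

    Each cell is one soma sphere (radius drawn uniformly in 5–10 µm) plus
    3–8 tapering neurites built from random-walk cylinder segments; all of a
    cell's voxels share one dye index (``dye_indices[i]``, default 0 for all).
    Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    lo = np.asarray(bounds_lo_um, dtype=float)
    hi = np.asarray(bounds_hi_um, dtype=float)
    max_soma = 10.0
    if np.any(hi - lo < 2 * max_soma + 2):
        raise ValueError(
            "bounds too small to place somata: need > "
            f"{2 * max_soma + 2:.0f} µm on every axis"
        )
    if dye_indices is None:
        dye_indices = [0] * n_cells
    rng = np.random.default_rng(seed)
    shapes: list = []
    for cell in range(n_cells):
        r_soma = rng.uniform(5.0, 10.0)
        c = rng.uniform(lo + r_soma + 1.0, hi - r_soma - 1.0)
        dye = int(dye_indices[cell])
        shapes.append(Sphere(tuple(c), r_soma, density, dye))
        n_neurites = int(rng.integers(3, 9))
        for _ in range(n_neurites):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p = c + direction * r_soma * 0.9
            radius = rng.uniform(1.0, 2.0)
            n_seg = int(rng.integers(3, 7))
            for _seg in range(n_seg):
                step_len = rng.uniform(5.0, 12.0)
                wobble = rng.normal(scale=0.45, size=3)
                direction = direction + wobble
                direction /= np.linalg.norm(direction)
                q = p + direction * step_len
                q = np.clip(q, lo + 0.5, hi - 0.5)
                shapes.append(Cylinder(tuple(p), tuple(q), radius, density, dye))
                p = q
                radius = max(radius * rng.uniform(0.6, 0.9), 0.4)
    return voxelize_primitives(shapes, voxel_size_um, lo, hi, sigma_s_elastic_cm)


def save_grid(grid: AnnotatedFluorescentVolumeGrid, prefix) -> None:
    """Write a grid as <prefix>_density.npy + <prefix>_dye.npy + <prefix>.json."""
    prefix = Path(prefix)
    np.save(str(prefix) + "_density.npy", grid.density)
    np.save(str(prefix) + "_dye.npy", grid.dye_index)
    meta = {
        "dims": list(grid.dims),
        "voxel_size_um": grid.voxel_size_um,
        "origin_um": grid.origin_um.tolist(),
        "sigma_s_elastic_cm": grid.sigma_s_elastic_cm,
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_grid(prefix) -> AnnotatedFluorescentVolumeGrid:
    prefix = Path(prefix)
    with open(str(prefix) + ".json") as fh:
        meta = json.load(fh)
    density = np.load(str(prefix) + "_density.npy")
    dye = np.load(str(prefix) + "_dye.npy")
    return AnnotatedFluorescentVolumeGrid(
        tuple(meta["dims"]),
        float(meta["voxel_size_um"]),
        np.asarray(meta["origin_um"]),
        density,
        dye,
        float(meta.get("sigma_s_elastic_cm", 0.0)),
    )


def grid_from_tiff(
    density_tiff,
    dye_tiff,
    voxel_size_um: float,
    origin_um=(0.0, 0.0, 0.0),
    sigma_s_elastic_cm: float = 0.0,
) -> AnnotatedFluorescentVolumeGrid:
    """Import a dense voxel grid from a multi-page TIFF pair (pages = z)."""
    import tifffile

    dens = np.asarray(tifffile.imread(density_tiff), dtype=float)
    dye = np.asarray(tifffile.imread(dye_tiff))
    # TIFF pages are (z, y, x); internal layout is (x, y, z)
    dens = np.transpose(dens, (2, 1, 0))
    dye = np.transpose(dye, (2, 1, 0)).astype(np.int32)
    return AnnotatedFluorescentVolumeGrid(
        dens.shape, voxel_size_um, np.asarray(origin_um, dtype=float), dens, dye,
        sigma_s_elastic_cm,
    )
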