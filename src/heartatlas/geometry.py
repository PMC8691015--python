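"""Geometric primitives shared by the whole pipeline.

Closed triangle meshes represent contoured structures in the patient
coordinate frame (+x patient-left, +y anterior, +z cranial, units mm).
Volumes of unions and intersections are computed on a common voxel grid:
a voxel belongs to a structure iff its *center* lies inside the closed
surface (parity of z-ray crossings).  Margin operations (the atlas's
1 cm outer shell and 2 cm inner margin) are Euclidean-distance erosions
on those voxel masks.

Volumes are reported in cm^3, all lengths in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import distance_transform_edt

__all__ = [
    "GridSpec",
    "BinaryMask",
    "MeshError",
    "require_watertight",
    "ensure_outward",
    "mesh_volume",
    "center_of_mass",
    "voxelize",
    "boolean_volumes",
    "inner_margin",
    "outer_shell",
    "make_primitive",
    "point_mesh_distance",
    "load_mesh",
    "save_mesh",
]

MM3_PER_CC = 1000.0


class MeshError(ValueError):
    """A mesh violates a contract (non-watertight, out of grid, ...)."""


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D grid. ``origin`` is the center of voxel (0,0,0), in mm.

    Voxel (i,j,k) has its center at ``origin + (i,j,k)*spacing`` and spans
    half a spacing to each side, so the grid covers
    ``[origin - spacing/2, origin + (shape - 1/2)*spacing]``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(int(n) < 1 or int(n) != n for n in self.shape):
            raise ValueError(f"shape must be positive integers, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def lower_corner(self) -> np.ndarray:
        return np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)

    @property
    def upper_corner(self) -> np.ndarray:
        return (
            np.asarray(self.origin)
            + (np.asarray(self.shape) - 0.5) * np.asarray(self.spacing)
        )

    def center_points(self) -> np.ndarray:
        """All voxel centers, shape ``(*self.shape, 3)``."""
        axes = [self.axis_centers(a) for a in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    @classmethod
    def covering(
        cls,
        bounds: np.ndarray,
        spacing: float | tuple[float, float, float],
        pad: float = 0.0,
    ) -> "GridSpec":
        """Smallest grid at ``spacing`` covering ``bounds`` (2x3 min/max, mm)
        plus ``pad`` mm on every side."""
        sp = np.broadcast_to(np.atleast_1d(np.asarray(spacing, float)), (3,)).copy()
        lo = np.asarray(bounds[0], float) - pad
        hi = np.asarray(bounds[1], float) + pad
        shape = np.maximum(np.ceil((hi - lo) / sp).astype(int), 1)
        # center the grid on the padded box
        origin = lo + 0.5 * sp - 0.5 * (shape * sp - (hi - lo))
        return cls(tuple(origin), tuple(sp), tuple(shape))


@dataclass
class BinaryMask:
    """Boolean occupancy on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, bool)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        return self.count * self.grid.voxel_volume_mm3 / MM3_PER_CC

    def centroid(self) -> np.ndarray:
        """Center of mass of the occupied voxels (mm)."""
        idx = np.argwhere(self.values)
        if idx.size == 0:
            raise ValueError("empty mask has no centroid")
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(
            self.grid.spacing
        )


# ---------------------------------------------------------------------------
# mesh basics


def require_watertight(mesh: trimesh.Trimesh) -> None:
    """Raise :class:`MeshError` listing boundary edges if not watertight."""
    if mesh.is_watertight:
        return
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts != 2]
    raise MeshError(
        f"mesh is not watertight: {len(boundary)} boundary/odd edges, "
        f"first few: {boundary[:5].tolist()}"
    )


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Return a copy with consistent outward orientation (positive volume).

    Inward-wound input is repaired with a warning rather than rejected.
    """
    require_watertight(mesh)
    if mesh.volume >= 0 and mesh.is_winding_consistent:
        return mesh
    fixed = mesh.copy()
    trimesh.repair.fix_normals(fixed)
    if fixed.volume < 0:
        fixed.invert()
    warnings.warn("mesh had inward/inconsistent winding; orientation repaired")
    return fixed


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in cm^3 (divergence theorem)."""
    mesh = ensure_outward(mesh)
    return float(abs(mesh.volume)) / MM3_PER_CC


def center_of_mass(mesh: trimesh.Trimesh) -> np.ndarray:
    """Solid (uniform-density) centroid in mm — not the vertex average."""
    mesh = ensure_outward(mesh)
    return np.asarray(mesh.center_mass, float)


# ---------------------------------------------------------------------------
# voxelization

# Deterministic sub-micron ray offsets: break exact vertex/edge hits without
# a measurable effect on volumes.  The two axes use incommensurate offsets so
# the shift is not parallel to any rational edge direction (e.g. the diagonal
# of a triangulated quad).
_RAY_EPS_X = 1e-7
_RAY_EPS_Y = 1e-7 * 1.6180339887498949  # golden ratio


def voxelize(mesh: trimesh.Trimesh, grid: GridSpec, clip: bool = False) -> BinaryMask:
    """Rasterize a closed mesh: voxel inside iff its center is inside.

    A vertical (z) ray is cast through every voxel-column center; surface
    crossings are accumulated per column and voxels with an odd number of
    crossings above their center are inside.  Fully vectorized over
    (face, column) candidate pairs.

    A mesh extending beyond the grid raises unless ``clip`` is set, in
    which case the mask is the intersection of the solid with the grid
    extent (used e.g. to restrict valve volumes to the dose-grid region).
    """
    mesh = ensure_outward(mesh)
    if not clip:
        lo, hi = mesh.bounds
        for ax, name in enumerate("xyz"):
            if lo[ax] < grid.lower_corner[ax] or hi[ax] > grid.upper_corner[ax]:
                raise MeshError(
                    f"mesh exceeds grid extent along {name}: mesh "
                    f"[{lo[ax]:.2f}, {hi[ax]:.2f}] vs grid "
                    f"[{grid.lower_corner[ax]:.2f}, {grid.upper_corner[ax]:.2f}]"
                )

    tri = mesh.triangles  # (F, 3, 3)
    xs = grid.axis_centers(0) + _RAY_EPS_X
    ys = grid.axis_centers(1) + _RAY_EPS_Y
    zc = grid.axis_centers(2)
    nx, ny, nz = grid.shape

    # candidate columns per face from the 2D bounding box
    fx = tri[:, :, 0]
    fy = tri[:, :, 1]
    i0 = np.searchsorted(xs, fx.min(axis=1), side="left")
    i1 = np.searchsorted(xs, fx.max(axis=1), side="right")
    j0 = np.searchsorted(ys, fy.min(axis=1), side="left")
    j1 = np.searchsorted(ys, fy.max(axis=1), side="right")
    ni = np.maximum(i1 - i0, 0)
    nj = np.maximum(j1 - j0, 0)
    npairs = ni * nj
    keep = npairs > 0
    if not keep.any():
        return BinaryMask(grid, np.zeros(grid.shape, bool))
    tri = tri[keep]
    i0, j0, ni, nj, npairs = i0[keep], j0[keep], ni[keep], nj[keep], npairs[keep]

    total = int(npairs.sum())
    face_of = np.repeat(np.arange(len(tri)), npairs)
    starts = np.concatenate(([0], np.cumsum(npairs)[:-1]))
    within = np.arange(total) - np.repeat(starts, npairs)
    ii = i0[face_of] + within // nj[face_of]
    jj = j0[face_of] + within % nj[face_of]
    px = xs[ii]
    py = ys[jj]

    a, b, c = tri[face_of, 0], tri[face_of, 1], tri[face_of, 2]
    d00x, d00y = b[:, 0] - a[:, 0], b[:, 1] - a[:, 1]
    d01x, d01y = c[:, 0] - a[:, 0], c[:, 1] - a[:, 1]
    denom = d00x * d01y - d01x * d00y
    apx, apy = px - a[:, 0], py - a[:, 1]
    nondeg = np.abs(denom) > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (apx * d01y - apy * d01x) / denom
        v = (d00x * apy - d00y * apx) / denom
        inside = nondeg & (u >= 0) & (v >= 0) & (u + v <= 1)
    if not inside.any():
        return BinaryMask(grid, np.zeros(grid.shape, bool))

    zcross = (
        a[inside, 2]
        + u[inside] * (b[inside, 2] - a[inside, 2])
        + v[inside] * (c[inside, 2] - a[inside, 2])
    )
    col = ii[inside] * ny + jj[inside]
    # crossing is above voxel k iff zc[k] < zcross; toggle the range [0, kup)
    kup = np.searchsorted(zc, zcross, side="left")
    diff = np.zeros(nx * ny * (nz + 1), np.int32)
    np.add.at(diff, col * (nz + 1), 1)
    np.add.at(diff, col * (nz + 1) + kup, -1)
    counts = np.cumsum(diff.reshape(nx, ny, nz + 1), axis=2)[:, :, :nz]
    return BinaryMask(grid, counts % 2 == 1)


def boolean_volumes(mask_a: BinaryMask, mask_b: BinaryMask) -> dict[str, float]:
    """Volumes (cm^3) of A, B, their intersection and union.

    Inclusion-exclusion is exact because all four come from integer voxel
    counts on the same grid.
    """
    if mask_a.grid != mask_b.grid:
        raise ValueError("masks live on different grids; no silent resampling")
    va = mask_a.values
    vb = mask_b.values
    scale = mask_a.grid.voxel_volume_mm3 / MM3_PER_CC
    n_a = int(va.sum())
    n_b = int(vb.sum())
    n_i = int((va & vb).sum())
    return {
        "volA": n_a * scale,
        "volB": n_b * scale,
        "volIntersection": n_i * scale,
        "volUnion": (n_a + n_b - n_i) * scale,
    }


# ---------------------------------------------------------------------------
# margins


def inner_margin(mask: BinaryMask, margin: float) -> BinaryMask:
    """Erode by a Euclidean ``margin`` (mm): keep voxels whose distance to
    the outside exceeds the margin.  Empty results warn, they do not raise."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return BinaryMask(mask.grid, mask.values.copy())
    dist = distance_transform_edt(mask.values, sampling=mask.grid.spacing)
    out = dist > margin
    if mask.count > 0 and not out.any():
        warnings.warn(f"inner margin {margin} mm erased the whole structure")
    return BinaryMask(mask.grid, out)


def outer_shell(mask: BinaryMask, thickness: float) -> BinaryMask:
    """The outer layer of ``thickness`` mm: mask minus its inner margin.

    Shell and eroded core partition the input exactly, voxel by voxel.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # full erosion is the expected limit
        core = inner_margin(mask, thickness)
    return BinaryMask(mask.grid, mask.values & ~core.values)


# ---------------------------------------------------------------------------
# primitives and distances


def make_primitive(kind: str, **params) -> trimesh.Trimesh:
    """Watertight, outward-oriented primitive mesh.

    kinds: ``sphere`` (radius, subdivisions=4), ``ellipsoid`` (semi_axes,
    subdivisions=4), ``cone`` (base_radius, height, sections=64),
    ``box`` (extents).  Dimensions in mm; all must be positive.
    """
    def _pos(name, value):
        arr = np.atleast_1d(np.asarray(value, float))
        if np.any(arr <= 0):
            raise ValueError(f"{kind}: {name} must be positive, got {value}")
        return value

    if kind == "sphere":
        mesh = trimesh.creation.icosphere(
            subdivisions=int(params.get("subdivisions", 4)),
            radius=_pos("radius", params["radius"]),
        )
    elif kind == "ellipsoid":
        axes = np.asarray(_pos("semi_axes", params["semi_axes"]), float)
        mesh = trimesh.creation.icosphere(
            subdivisions=int(params.get("subdivisions", 4)), radius=1.0
        )
        mesh.apply_scale(axes)
    elif kind == "cone":
        mesh = trimesh.creation.cone(
            radius=_pos("base_radius", params["base_radius"]),
            height=_pos("height", params["height"]),
            sections=int(params.get("sections", 64)),
        )
    elif kind == "box":
        mesh = trimesh.creation.box(extents=_pos("extents", params["extents"]))
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    return ensure_outward(mesh)


def point_mesh_distance(points: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface (mm).

    Closest point on each triangle via the barycentric region method,
    vectorized over (point, triangle) pairs; fine for the small meshes
    (valve cones/spheres) this package queries.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    tri = mesh.triangles  # (F, 3, 3)
    a = tri[None, :, 0]
    b = tri[None, :, 1]
    c = tri[None, :, 2]
    p = pts[:, None, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("pfk,pfk->pf", ab, ap)
    d2 = np.einsum("pfk,pfk->pf", ac, ap)
    bp = p - b
    d3 = np.einsum("pfk,pfk->pf", ab, bp)
    d4 = np.einsum("pfk,pfk->pf", ac, bp)
    cp = p - c
    d5 = np.einsum("pfk,pfk->pf", ab, cp)
    d6 = np.einsum("pfk,pfk->pf", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = d1 / (d1 - d3)
        w_edge_ac = d2 / (d2 - d6)
        w_edge_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    # default: interior projection
    v = v_in
    w = w_in
    # region masks, applied in the standard order
    r_a = (d1 <= 0) & (d2 <= 0)
    r_b = (d3 >= 0) & (d4 <= d3)
    r_c = (d6 >= 0) & (d5 <= d6)
    r_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    r_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    r_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    v = np.where(r_bc, 1.0 - w_edge_bc, v)
    w = np.where(r_bc, w_edge_bc, w)
    v = np.where(r_ac, 0.0, v)
    w = np.where(r_ac, w_edge_ac, w)
    v = np.where(r_ab, v_edge_ab, v)
    w = np.where(r_ab, 0.0, w)
    v = np.where(r_c, 0.0, v)
    w = np.where(r_c, 1.0, w)
    v = np.where(r_b, 1.0, v)
    w = np.where(r_b, 0.0, w)
    v = np.where(r_a, 0.0, v)
    w = np.where(r_a, 0.0, w)

    closest = a + v[..., None] * ab + w[..., None] * ac
    d = np.linalg.norm(p - closest, axis=-1)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# I/O


def load_mesh(path) -> trimesh.Trimesh:
    """Load a PLY/STL surface mesh (mm) and enforce outward orientation."""
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshError(f"{path} did not contain a single triangle mesh")
    return ensure_outward(mesh)


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write PLY (binary) or STL depending on the file suffix."""
    mesh.export(str(path))
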