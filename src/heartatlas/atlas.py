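"""Surrogate-volume construction for the heart atlas.

From a complete-heart contour plus two landmarks the atlas derives six
substructures that stand in for cardiac organs at risk that are poorly
visible on low-quality CT:

* aortic valve        — cone from the aortic root, 3 cm caudal extent
* pulmonary valve     — sphere around a truncus-pulmonalis point, grown
                        until it almost touches the aortic valve
* myocardium          — 1 cm outer shell of the heart below the aortic root
* left/right anterior myocardium — anterior half of that shell, split at a
                        sagittal plane through the heart centroid
* deep structures     — heart eroded by a symmetric 2 cm inner margin

Valve surrogates are meshes by construction; shell/margin structures are
built on a voxel grid and converted back to watertight surface meshes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .geometry import (
    BinaryMask,
    GridSpec,
    ensure_outward,
    inner_margin,
    make_primitive,
    outer_shell,
    point_mesh_distance,
    voxelize,
)

__all__ = [
    "STRUCTURES",
    "Landmarks",
    "StructureSet",
    "AtlasParams",
    "build_aortic_valve",
    "build_pulmonary_valve",
    "build_myocardium",
    "split_anterior_walls",
    "build_deep_structures",
    "mask_to_mesh",
    "build_structure_set",
]

#: Fixed 7-name structure vocabulary.
STRUCTURES = (
    "heart",
    "aortic_valve",
    "pulmonary_valve",
    "myocardium",
    "left_anterior_myocardium",
    "right_anterior_myocardium",
    "deep_structures",
)


@dataclass
class Landmarks:
    """Atlas landmarks in mm (patient frame).

    ``heart_axis_lr`` is the unit left-right axis used for the
    left/right anterior wall split; +x is patient-left.
    """

    aortic_root_center: np.ndarray
    truncus_point: np.ndarray
    heart_axis_lr: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )

    def __post_init__(self):
        self.aortic_root_center = np.asarray(self.aortic_root_center, float)
        self.truncus_point = np.asarray(self.truncus_point, float)
        axis = np.asarray(self.heart_axis_lr, float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("heart_axis_lr must be a nonzero vector")
        self.heart_axis_lr = axis / norm
        if np.allclose(self.aortic_root_center, self.truncus_point):
            raise ValueError("truncus point must differ from the aortic root")

    def to_dict(self) -> dict:
        return {
            "aortic_root_center": self.aortic_root_center.tolist(),
            "truncus_point": self.truncus_point.tolist(),
            "heart_axis_lr": self.heart_axis_lr.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        return cls(
            np.asarray(d["aortic_root_center"], float),
            np.asarray(d["truncus_point"], float),
            np.asarray(d.get("heart_axis_lr", [1.0, 0.0, 0.0]), float),
        )


@dataclass
class StructureSet:
    """All atlas structures of one (patient, observer) as surface meshes."""

    patient_id: str
    observer_id: str
    structures: dict[str, trimesh.Trimesh]

    def __post_init__(self):
        if "heart" not in self.structures:
            raise ValueError("StructureSet must contain the complete heart")
        unknown = set(self.structures) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structure names: {sorted(unknown)}")


@dataclass
class AtlasParams:
    """Tunable atlas-construction parameters (mm)."""

    cone_base_radius: float = 21.0   # gives the ~14 cm^3 surrogate volume
                                     # observed for the conical aortic valve
    cone_height: float = 30.0        # "3 cm in the caudal direction"
    cone_apex: str = "caudal"        # or "cranial"
    valve_gap: float = 2.0           # "almost touches" clearance
    shell_thickness: float = 10.0    # myocardium outer layer
    deep_margin: float = 20.0        # symmetric inner margin
    grid_spacing: float = 1.0        # construction voxel grid, isotropic
    grid_pad: float = 4.0


def build_aortic_valve(
    landmarks: Landmarks,
    base_radius: float = 21.0,
    height: float = 30.0,
    apex: str = "caudal",
    sections: int = 64,
) -> trimesh.Trimesh:
    """Conical aortic-valve surrogate spanning ``height`` mm caudal of the
    aortic root center; default orientation puts the apex caudal."""
    cone = make_primitive(
        "cone", base_radius=base_radius, height=height, sections=sections
    )
    # trimesh cones have the base at z=0 and apex at z=height
    if apex == "caudal":
        cone.apply_transform(
            trimesh.transformations.rotation_matrix(np.pi, [1.0, 0.0, 0.0])
        )  # apex now at z=-height, base at z=0
        cone.apply_translation(landmarks.aortic_root_center)
    elif apex == "cranial":
        cone.apply_translation(
            landmarks.aortic_root_center - np.array([0.0, 0.0, height])
        )
    else:
        raise ValueError("apex must be 'caudal' or 'cranial'")
    return ensure_outward(cone)


def build_pulmonary_valve(
    landmarks: Landmarks,
    aortic_valve: trimesh.Trimesh,
    gap: float = 2.0,
    subdivisions: int = 3,
) -> trimesh.Trimesh:
    """Sphere around the truncus point grown until ``gap`` mm short of the
    aortic-valve surface."""
    dist = float(point_mesh_distance(landmarks.truncus_point, aortic_valve)[0])
    radius = dist - gap
    if radius <= 0:
        raise ValueError(
            "truncus landmark lies inside or too close to the aortic valve "
            f"(surface distance {dist:.2f} mm, gap {gap:.2f} mm)"
        )
    sphere = make_primitive("sphere", radius=radius, subdivisions=subdivisions)
    sphere.apply_translation(landmarks.truncus_point)
    return sphere


def build_myocardium(
    heart: BinaryMask,
    aortic_valve: trimesh.Trimesh,
    thickness: float = 10.0,
) -> BinaryMask:
    """1 cm outer shell of the heart, restricted to below the aortic root
    plane (the cranial cap of the valve cone)."""
    if heart.count == 0:
        raise ValueError("heart mask is empty")
    shell = outer_shell(heart, thickness)
    z_top = float(aortic_valve.bounds[1, 2])
    zc = heart.grid.axis_centers(2)
    below = zc < z_top
    values = shell.values & below[None, None, :]
    if not values.any():
        raise ValueError("myocardium is empty (root plane below the heart?)")
    return BinaryMask(heart.grid, values)


def split_anterior_walls(
    myocardium: BinaryMask,
    landmarks: Landmarks,
    heart_center: np.ndarray | None = None,
) -> dict[str, BinaryMask]:
    """Left/right anterior wall: anterior (+y of the heart centroid) half of
    the myocardium, split by the sagittal plane through the centroid with
    normal ``heart_axis_lr``; +x is patient-left."""
    if myocardium.count == 0:
        raise ValueError("myocardium mask is empty")
    center = (
        np.asarray(heart_center, float)
        if heart_center is not None
        else myocardium.centroid()
    )
    grid = myocardium.grid
    pts = grid.center_points()
    anterior = pts[..., 1] > center[1]
    side = (pts - center) @ landmarks.heart_axis_lr
    ant_myo = myocardium.values & anterior
    if not ant_myo.any():
        raise ValueError("anterior myocardium region is empty")
    return {
        "left_anterior": BinaryMask(grid, ant_myo & (side > 0)),
        "right_anterior": BinaryMask(grid, ant_myo & (side <= 0)),
    }


def build_deep_structures(heart: BinaryMask, margin: float = 20.0) -> BinaryMask:
    """Deep cardiac structures: symmetric ``margin`` mm inner margin."""
    if heart.count == 0:
        raise ValueError("heart mask is empty")
    return inner_margin(heart, margin)


def mask_to_mesh(mask: BinaryMask) -> trimesh.Trimesh:
    """Watertight surface mesh of a voxel mask (marching cubes at 0.5)."""
    if mask.count == 0:
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.values, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=mask.grid.spacing)
    verts = verts + np.asarray(mask.grid.origin) - np.asarray(mask.grid.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def build_structure_set(
    heart_mesh: trimesh.Trimesh,
    landmarks: Landmarks,
    params: AtlasParams | None = None,
    patient_id: str = "p00",
    observer_id: str = "obs0",
) -> StructureSet:
    """Construct all six surrogate substructures from a heart contour.

    Shell/margin structures are built on an isotropic voxel grid covering
    the heart and converted back to meshes; valves are analytic meshes.
    Deterministic given (mesh, landmarks, params).
    """
    params = params or AtlasParams()
    aortic = build_aortic_valve(
        landmarks,
        base_radius=params.cone_base_radius,
        height=params.cone_height,
        apex=params.cone_apex,
    )
    pulmonary = build_pulmonary_valve(landmarks, aortic, gap=params.valve_gap)

    grid = GridSpec.covering(
        heart_mesh.bounds, params.grid_spacing, pad=params.grid_pad
    )
    heart_mask = voxelize(heart_mesh, grid)
    myo = build_myocardium(heart_mask, aortic, thickness=params.shell_thickness)
    walls = split_anterior_walls(myo, landmarks, heart_center=heart_mask.centroid())
    deep = build_deep_structures(heart_mask, margin=params.deep_margin)

    structures = {
        "heart": ensure_outward(heart_mesh),
        "aortic_valve": aortic,
        "pulmonary_valve": pulmonary,
        "myocardium": mask_to_mesh(myo),
    }
    for key, name in [
        ("left_anterior", "left_anterior_myocardium"),
        ("right_anterior", "right_anterior_myocardium"),
    ]:
        if walls[key].count > 0:
            structures[name] = mask_to_mesh(walls[key])
        else:
            warnings.warn(f"{name} is empty for {patient_id}/{observer_id}")
    if deep.count > 0:
        structures["deep_structures"] = mask_to_mesh(deep)
    else:
        warnings.warn(f"deep_structures empty for {patient_id}/{observer_id}")
    return StructureSet(patient_id, observer_id, structures)
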