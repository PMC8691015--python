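"""Synthetic multi-patient, multi-observer cohort generator.

The study design emulated here: 16 patients, each contoured independently
by 6 observers on CT with a slice-thickness mix of 10 mm (3 patients),
7.5 mm (4), 5 mm (1) and 3 mm (8); hearts around 700 cm^3; a tangential
two-field dose distribution with 50 Gy prescription whose steep field
border crosses the anterior-left heart.

Per patient a smooth ellipsoid-based "true" heart is drawn.  Each
observer sees a perturbed version: a smooth random radial displacement
field (truncated spherical-harmonic coefficients), a cranio-caudal extent
shift quantized to the CT slice planes, and Gaussian jitter on the valve
landmarks.  The atlas module then builds all six substructures from the
perturbed heart, so downstream agreement/dose/variability stages run on
data with the same statistical structure the analysis assumes.

Every random draw comes from a substream keyed by
(master_seed, purpose, patient, observer), so regeneration is
reproducible and order-independent.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .atlas import AtlasParams, Landmarks, StructureSet, build_structure_set
from .dosimetry import DoseGrid
from .geometry import GridSpec, ensure_outward, save_mesh, voxelize

__all__ = [
    "CohortConfig",
    "generate_heart",
    "perturb_heart",
    "simulate_observer",
    "simulate_dose",
    "generate_cohort",
    "calibrate_observer_sd",
    "save_dose",
    "load_dose",
]

# substream purpose codes
_P_HEART = 1
_P_OBSERVER = 2
_P_DOSE = 3


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort (lengths mm)."""

    n_patients: int = 16
    n_observers: int = 6
    #: (slice thickness mm, number of patients) pairs
    slice_thickness_mix: tuple = ((10.0, 3), (7.5, 4), (5.0, 1), (3.0, 8))
    heart_volume_range: tuple = (550.0, 850.0)  # cm^3
    observer_sd: float = 2.5        # radial contour perturbation scale, mm
    landmark_sd: float = 3.5        # aortic-root landmark jitter per axis, mm
    truncus_sd: float = 5.0         # truncus landmark jitter per axis, mm
                                    # (worse visibility than the aortic root)
    cone_radius_sd: float = 1.5     # per-observer aortic cone base-radius
                                    # jitter, mm (slice-wise contouring of
                                    # the cone varies its apparent size)
    shell_thickness_sd: float = 0.5  # per-observer execution jitter of the
                                     # 1 cm myocardial shell rule, mm
    deep_margin_sd: float = 1.25     # per-observer execution jitter of the
                                     # 2 cm inner-margin rule, mm
    shape_sd: float = 2.0           # per-patient shape individuality, mm
    # dose model
    prescription_gy: float = 50.0
    penumbra_mm: float = 2.5        # logistic penumbra scale
    base_gy: float = 1.2            # out-of-field dose at the field edge
    base_decay_mm: float = 40.0     # exponential decay length out of field
    #: per-patient target heart fraction with >= 5 Gy is drawn uniformly
    #: from this range (mean ~0.135, matching typical tangential anatomy)
    in_field_range: tuple = (0.05, 0.22)
    dose_spacing: float = 2.5
    dose_pad: float = 30.0
    master_seed: int = 20211220
    atlas: AtlasParams = field(default_factory=AtlasParams)

    def __post_init__(self):
        if self.n_patients < 1 or self.n_observers < 1:
            raise ValueError("need at least one patient and one observer")
        for name in ("observer_sd", "landmark_sd", "penumbra_mm",
                     "dose_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.heart_volume_range[0] <= 0 or (
            self.heart_volume_range[1] < self.heart_volume_range[0]
        ):
            raise ValueError("invalid heart_volume_range")

    def slice_thicknesses(self) -> list[float]:
        """Per-patient slice thickness; the mix is cycled if n_patients
        differs from the sum of the configured counts."""
        expanded = [t for t, cnt in self.slice_thickness_mix for _ in range(cnt)]
        return [expanded[i % len(expanded)] for i in range(self.n_patients)]

    def patient_ids(self) -> list[str]:
        return [f"p{i:02d}" for i in range(self.n_patients)]

    def observer_ids(self) -> list[str]:
        return [f"obs{i}" for i in range(self.n_observers)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slice_thickness_mix"] = [list(p) for p in self.slice_thickness_mix]
        d["heart_volume_range"] = list(self.heart_volume_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "atlas" in d and isinstance(d["atlas"], dict):
            d["atlas"] = AtlasParams(**d["atlas"])
        if "slice_thickness_mix" in d:
            d["slice_thickness_mix"] = tuple(
                (float(t), int(c)) for t, c in d["slice_thickness_mix"]
            )
        if "heart_volume_range" in d:
            d["heart_volume_range"] = tuple(d["heart_volume_range"])
        return cls(**d)


def _rng(config: CohortConfig, purpose: int, patient: int = 0,
         observer: int = 0, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(config.master_seed), purpose, patient, observer, extra]
        )
    )


# ---------------------------------------------------------------------------
# random smooth radial fields


def _real_sph_harm_basis(directions: np.ndarray, l_max: int) -> np.ndarray:
    """Real orthonormal spherical-harmonic basis evaluated at unit vectors.

    Returns an array (n_points, n_modes) with n_modes = (l_max + 1)^2.
    """
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.real)
            elif m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.imag)
            else:
                cols.append(ylm.real)
    return np.stack(cols, axis=1)


def _radial_field(directions: np.ndarray, rng: np.random.Generator,
                  sd: float, l_max: int = 3) -> np.ndarray:
    """Zero-mean smooth random field with pointwise standard deviation
    ``sd`` mm, from iid normal coefficients on the real SH basis."""
    n_modes = (l_max + 1) ** 2
    coeff = rng.normal(0.0, sd * np.sqrt(4.0 * np.pi / n_modes), n_modes)
    return _real_sph_harm_basis(directions, l_max) @ coeff


# ---------------------------------------------------------------------------
# truth anatomy


def generate_heart(
    config: CohortConfig, patient_index: int
) -> tuple[trimesh.Trimesh, Landmarks]:
    """Synthetic "true" heart mesh plus landmarks for one patient.

    Smooth perturbed ellipsoid rescaled to a volume drawn uniformly from
    ``heart_volume_range``; the aortic root sits 5 mm caudal of the
    cranial pole, the truncus point 25.1 mm anterior-left of it at root
    level, placed so the default pulmonary-valve sphere comes out near a
    realistic 8 cm^3.  Deterministic per (master_seed, patient_index).
    """
    rng = _rng(config, _P_HEART, patient_index)
    target_cc = rng.uniform(*config.heart_volume_range)
    ry = 0.85 + rng.normal(0.0, 0.05)
    rz = 1.15 + rng.normal(0.0, 0.05)
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    mesh.apply_scale([1.0, max(ry, 0.5), max(rz, 0.5)])
    # uniform scale to the target volume, then shape individuality
    mesh.apply_scale((target_cc * 1000.0 / mesh.volume) ** (1.0 / 3.0))
    verts = mesh.vertices.view(np.ndarray).copy()
    radii = np.linalg.norm(verts, axis=1)
    dirs = verts / radii[:, None]
    bump = _radial_field(dirs, rng, config.shape_sd, l_max=2)
    mesh = trimesh.Trimesh(
        vertices=dirs * (radii + bump)[:, None], faces=mesh.faces, process=False
    )
    mesh.apply_scale((target_cc * 1000.0 / mesh.volume) ** (1.0 / 3.0))
    mesh = ensure_outward(mesh)

    z_top = float(mesh.bounds[1, 2])
    root = np.array([0.0, 0.0, z_top - 5.0])
    truncus = root + np.array([25.1, 25.1, 0.0])
    return mesh, Landmarks(root, truncus)


def perturb_heart(
    truth_mesh: trimesh.Trimesh,
    truth_landmarks: Landmarks,
    rng: np.random.Generator,
    slice_thickness: float,
    config: CohortConfig,
    max_tries: int = 5,
) -> tuple[trimesh.Trimesh, Landmarks]:
    """One observer's contour of the heart plus their landmark estimates.

    (i) smooth random radial displacement (SH l<=3 coefficients with
    pointwise sd ``observer_sd``); (ii) cranial and caudal extents each
    shifted ~N(0, (slice_thickness/2)^2) then quantized to slice planes;
    (iii) landmarks jittered ~N(0, landmark_sd^2) per axis.
    """
    center = np.asarray(truth_mesh.center_mass, float)
    for attempt in range(max_tries):
        verts = truth_mesh.vertices.view(np.ndarray) - center
        radii = np.linalg.norm(verts, axis=1)
        dirs = verts / radii[:, None]
        disp = _radial_field(dirs, rng, config.observer_sd, l_max=3)
        new = dirs * (radii + disp)[:, None]

        # cranio-caudal extent shift, quantized to the CT slice planes
        z = new[:, 2]
        z_top, z_bot = float(z.max()), float(z.min())
        t = slice_thickness
        new_top = np.round((z_top + rng.normal(0.0, t / 2.0)) / t) * t
        new_bot = np.round((z_bot + rng.normal(0.0, t / 2.0)) / t) * t
        if new_top - new_bot > 0.5 * (z_top - z_bot):
            scale = (new_top - new_bot) / (z_top - z_bot)
            new[:, 2] = new_bot + (z - z_bot) * scale
        mesh = trimesh.Trimesh(
            vertices=new + center, faces=truth_mesh.faces, process=False
        )
        if mesh.is_watertight and mesh.volume > 0:
            break
        warnings.warn(f"observer perturbation attempt {attempt} degenerate; "
                      "resampling")
    landmarks = Landmarks(
        truth_landmarks.aortic_root_center + rng.normal(0, config.landmark_sd, 3),
        truth_landmarks.truncus_point + rng.normal(0, config.truncus_sd, 3),
        truth_landmarks.heart_axis_lr,
    )
    return ensure_outward(mesh), landmarks


def simulate_observer(
    truth_mesh: trimesh.Trimesh,
    truth_landmarks: Landmarks,
    config: CohortConfig,
    patient_index: int,
    observer_index: int,
    slice_thickness: float,
) -> StructureSet:
    """Full observer simulation: perturbed heart + atlas substructures."""
    from dataclasses import replace

    rng = _rng(config, _P_OBSERVER, patient_index, observer_index)
    heart, landmarks = perturb_heart(
        truth_mesh, truth_landmarks, rng, slice_thickness, config
    )
    # per-observer execution of the geometric atlas rules: the cone size,
    # shell thickness and inner margin are judged slice by slice and vary
    params = replace(
        config.atlas,
        cone_base_radius=max(
            float(rng.normal(config.atlas.cone_base_radius,
                             config.cone_radius_sd)),
            5.0,
        ),
        shell_thickness=max(
            float(rng.normal(config.atlas.shell_thickness,
                             config.shell_thickness_sd)),
            2.0,
        ),
        deep_margin=max(
            float(rng.normal(config.atlas.deep_margin,
                             config.deep_margin_sd)),
            5.0,
        ),
    )
    for attempt in range(10):
        try:
            return build_structure_set(
                heart,
                landmarks,
                params=params,
                patient_id=f"p{patient_index:02d}",
                observer_id=f"obs{observer_index}",
            )
        except ValueError as exc:
            # e.g. jittered truncus inside the aortic valve: redraw landmarks
            warnings.warn(
                f"structure build failed (attempt {attempt}): {exc}; "
                "re-jittering landmarks"
            )
            landmarks = Landmarks(
                truth_landmarks.aortic_root_center
                + rng.normal(0, config.landmark_sd, 3),
                truth_landmarks.truncus_point
                + rng.normal(0, config.truncus_sd, 3),
                truth_landmarks.heart_axis_lr,
            )
    raise RuntimeError(
        f"could not build a valid structure set for patient {patient_index}, "
        f"observer {observer_index}"
    )


# ---------------------------------------------------------------------------
# dose


def simulate_dose(
    truth_mesh: trimesh.Trimesh,
    config: CohortConfig,
    patient_index: int = 0,
) -> DoseGrid:
    """Tangential-field surrogate dose distribution for one patient.

    dose(x) = Rx * sigmoid(s/w) + base * exp(min(s,0)/lambda) with s the
    signed distance to the field-edge plane (normal pointing
    anterior-left, slightly randomized per patient).  The plane offset is
    found by bisection so that the fraction of the true heart receiving
    >= 5 Gy matches a per-patient target drawn from ``in_field_range`` —
    the steep gradient then crosses the anterior-left heart as in
    tangential breast irradiation, with realistic anatomy-to-anatomy
    variation in how deeply the heart enters the fields.
    """
    rng = _rng(config, _P_DOSE, patient_index)
    target_fraction = float(rng.uniform(*config.in_field_range))
    grid = GridSpec.covering(
        truth_mesh.bounds, config.dose_spacing, pad=config.dose_pad
    )
    heart_mask = voxelize(truth_mesh, grid)
    pts = grid.center_points().reshape(-1, 3)

    angle = np.deg2rad(45.0 + rng.normal(0.0, 5.0))
    normal = np.array([np.sin(angle), np.cos(angle), 0.0])
    proj = pts @ normal
    heart_proj = proj.reshape(grid.shape)[heart_mask.values]

    def dose_at(s):
        in_field = config.prescription_gy / (1.0 + np.exp(-s / config.penumbra_mm))
        scatter = config.base_gy * np.exp(np.minimum(s, 0.0) / config.base_decay_mm)
        return in_field + scatter

    def frac_ge5(offset):
        return float(np.mean(dose_at(heart_proj - offset) >= 5.0))

    lo, hi = float(heart_proj.min()) - 20.0, float(heart_proj.max()) + 20.0
    if frac_ge5(lo) < target_fraction:
        warnings.warn("field plane cannot reach the target in-field fraction")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac_ge5(mid) > target_fraction:
            lo = mid
        else:
            hi = mid
    offset = 0.5 * (lo + hi)
    dose = dose_at(proj - offset).reshape(grid.shape)
    return DoseGrid(grid, dose)


# ---------------------------------------------------------------------------
# dose grid I/O (NRRD via SimpleITK)


def save_dose(dose: DoseGrid, path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(dose.dose.T, np.float32))
    img.SetSpacing(tuple(dose.grid.spacing))
    img.SetOrigin(tuple(dose.grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def load_dose(path) -> DoseGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T.astype(float)
    grid = GridSpec(tuple(img.GetOrigin()), tuple(img.GetSpacing()), arr.shape)
    return DoseGrid(grid, arr)


# ---------------------------------------------------------------------------
# cohort on disk


def generate_cohort(config: CohortConfig, out_dir, force: bool = False) -> Path:
    """Write the full synthetic dataset: per patient the truth mesh,
    landmarks and dose grid; per (patient, observer) a structure set of
    PLY meshes; plus a manifest.  Fully determined by ``master_seed``."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    thicknesses = config.slice_thicknesses()
    manifest = {"config": config.to_dict(), "patients": []}
    for pi, pid in enumerate(config.patient_ids()):
        pdir = out / pid
        pdir.mkdir()
        truth, landmarks = generate_heart(config, pi)
        save_mesh(truth, pdir / "truth_heart.ply")
        (pdir / "landmarks.json").write_text(
            json.dumps(landmarks.to_dict(), sort_keys=True, indent=1)
        )
        dose = simulate_dose(truth, config, pi)
        save_dose(dose, pdir / "dose.nrrd")
        entry = {
            "patient_id": pid,
            "slice_thickness": thicknesses[pi],
            "observers": {},
        }
        for oi, oid in enumerate(config.observer_ids()):
            odir = pdir / "observers" / oid
            odir.mkdir(parents=True)
            sset = simulate_observer(truth, landmarks, config, pi, oi,
                                     thicknesses[pi])
            files = {}
            for name, mesh in sset.structures.items():
                save_mesh(mesh, odir / f"{name}.ply")
                files[name] = str((odir / f"{name}.ply").relative_to(out))
            entry["observers"][oid] = files
        manifest["patients"].append(entry)
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )
    return out


# ---------------------------------------------------------------------------
# closed-loop calibration


def heart_volume_cv(config: CohortConfig) -> float:
    """Heart-volume CV (fraction) recovered from perturbed heart meshes
    only — the cheap inner loop of :func:`calibrate_observer_sd`."""
    import pandas as pd

    from .variability import lognormal_cv

    rows = []
    thicknesses = config.slice_thicknesses()
    for pi, pid in enumerate(config.patient_ids()):
        truth, landmarks = generate_heart(config, pi)
        for oi, oid in enumerate(config.observer_ids()):
            rng = _rng(config, _P_OBSERVER, pi, oi)
            mesh, _ = perturb_heart(truth, landmarks, rng, thicknesses[pi],
                                    config)
            rows.append(
                {
                    "structure": "heart",
                    "patient": pid,
                    "observer": oid,
                    "value": mesh.volume / 1000.0,
                }
            )
    est = lognormal_cv(pd.DataFrame(rows))[0]
    return est.estimate


def calibrate_observer_sd(
    target_cv: float,
    config: CohortConfig,
    lo: float = 0.1,
    hi: float = 15.0,
    tol: float = 0.001,
    max_iter: int = 12,
) -> float:
    """Find observer_sd (mm) whose cohort recovers ``target_cv`` (fraction)
    for heart volume, by bisection; the recovered CV is monotone in the
    perturbation scale."""
    from dataclasses import replace

    if not (0.0 < target_cv < 0.5):
        raise ValueError("target_cv should be a fraction in (0, 0.5)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cv = heart_volume_cv(replace(config, observer_sd=mid))
        if abs(cv - target_cv) < tol:
            return mid
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
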