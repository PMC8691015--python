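"""Pairwise spatial agreement between observers' contours.

For every unordered observer pair and structure the pipeline computes

* volume overlap — Dice (DSC) and Jaccard (JSC) coefficients from
  intersection/union volumes on a shared voxel grid,
* distances — Euclidean distance of the centers of mass (DCOM), average
  surface distance (ASD) and Hausdorff distance (HD) from the set of
  vertex-by-vertex Euclidean distances between the two meshes.

Per-structure summaries are unweighted means over observer pairs and
patients; undefined records (empty structures) are counted, not imputed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .geometry import GridSpec, boolean_volumes, center_of_mass, voxelize

__all__ = [
    "PairwiseAgreement",
    "observer_pairs",
    "overlap_metrics",
    "distance_metrics",
    "pairwise_agreement",
    "structure_set_agreement",
    "aggregate",
]

METRICS = ("dsc", "jsc", "dcom", "asd", "hd")


@dataclass
class PairwiseAgreement:
    """Agreement record for one (patient, structure, observer pair)."""

    patient_id: str
    structure: str
    observer_a: str
    observer_b: str
    dsc: float
    jsc: float
    dcom: float
    asd: float
    hd: float


def observer_pairs(observers: list) -> list[tuple]:
    """All n(n-1)/2 unordered observer pairs, lexicographically ordered."""
    unique = sorted(set(observers))
    if len(unique) < 2:
        raise ValueError(f"need at least 2 distinct observers, got {unique}")
    return list(itertools.combinations(unique, 2))


def overlap_metrics(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    spacing: float = 1.0,
    grid: GridSpec | None = None,
) -> dict[str, float]:
    """Dice and Jaccard from voxelized intersection/union volumes.

    DSC = 2 V∩ / (V_A + V_B), JSC = V∩ / V∪; both derive from the same
    voxel counts so DSC = 2 JSC / (1 + JSC) holds to machine precision.
    """
    if grid is None:
        bounds = np.array(
            [
                np.minimum(mesh_a.bounds[0], mesh_b.bounds[0]),
                np.maximum(mesh_a.bounds[1], mesh_b.bounds[1]),
            ]
        )
        grid = GridSpec.covering(bounds, spacing, pad=2 * spacing)
    vols = boolean_volumes(voxelize(mesh_a, grid), voxelize(mesh_b, grid))
    va, vb = vols["volA"], vols["volB"]
    if va + vb == 0:
        raise ValueError("both structures are empty; overlap undefined")
    return {
        "dsc": 2.0 * vols["volIntersection"] / (va + vb),
        "jsc": (
            vols["volIntersection"] / vols["volUnion"]
            if vols["volUnion"] > 0
            else 0.0
        ),
    }


def _resampled_vertices(mesh: trimesh.Trimesh, max_edge: float) -> np.ndarray:
    if max_edge is None:
        return mesh.vertices.view(np.ndarray)
    return mesh.subdivide_to_size(max_edge).vertices.view(np.ndarray)


def distance_metrics(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    resample_max_edge: float | None = 2.0,
    verbose: bool = False,
) -> dict[str, float]:
    """DCOM, ASD and HD between two contour meshes.

    Vertex-to-vertex distances are tessellation dependent, so both meshes
    are refined to edges <= ``resample_max_edge`` mm first (pass ``None``
    to use the raw vertices, e.g. against a brute-force oracle).  ASD is
    the symmetrized mean of the two directed mean distances, HD the
    maximum over both directions; DCOM uses solid centroids.
    """
    if len(mesh_a.vertices) == 0 or len(mesh_b.vertices) == 0:
        raise ValueError("empty vertex set")
    dcom = float(np.linalg.norm(center_of_mass(mesh_a) - center_of_mass(mesh_b)))
    va = _resampled_vertices(mesh_a, resample_max_edge)
    vb = _resampled_vertices(mesh_b, resample_max_edge)
    d_ab, _ = cKDTree(vb).query(va)
    d_ba, _ = cKDTree(va).query(vb)
    out = {
        "dcom": dcom,
        "asd": 0.5 * (float(d_ab.mean()) + float(d_ba.mean())),
        "hd": max(float(d_ab.max()), float(d_ba.max())),
    }
    if verbose:
        out["asd_ab"] = float(d_ab.mean())
        out["asd_ba"] = float(d_ba.mean())
    return out


def pairwise_agreement(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    spacing: float = 1.0,
    grid: GridSpec | None = None,
    resample_max_edge: float | None = 2.0,
) -> dict[str, float]:
    """All five agreement metrics for one mesh pair."""
    out = overlap_metrics(mesh_a, mesh_b, spacing=spacing, grid=grid)
    out.update(distance_metrics(mesh_a, mesh_b, resample_max_edge=resample_max_edge))
    return out


def structure_set_agreement(
    structure_sets: list,
    spacing: float = 1.0,
    resample_max_edge: float | None = 2.0,
) -> pd.DataFrame:
    """Tidy table of pairwise agreement for one patient's structure sets.

    One row per (structure, observer pair); structures missing for either
    observer of a pair yield a row of NaN metrics (recorded, not imputed).
    Masks are voxelized once per (observer, structure) on a common grid.
    """
    if not structure_sets:
        raise ValueError("no structure sets given")
    patient_id = structure_sets[0].patient_id
    by_obs = {s.observer_id: s for s in structure_sets}
    pairs = observer_pairs(list(by_obs))

    all_bounds = np.array(
        [
            m.bounds[i]
            for s in structure_sets
            for m in s.structures.values()
            for i in (0, 1)
        ]
    )
    grid = GridSpec.covering(
        np.array([all_bounds.min(axis=0), all_bounds.max(axis=0)]),
        spacing,
        pad=2 * spacing,
    )

    from .atlas import STRUCTURES

    present = {name for s in structure_sets for name in s.structures}
    names = [n for n in STRUCTURES if n in present]
    names += sorted(present - set(names))
    masks: dict[tuple, object] = {}
    for obs, sset in by_obs.items():
        for name, mesh in sset.structures.items():
            masks[obs, name] = voxelize(mesh, grid)

    rows = []
    for name in names:
        for a, b in pairs:
            row = {
                "patient_id": patient_id,
                "structure": name,
                "observer_a": a,
                "observer_b": b,
            }
            mesh_a = by_obs[a].structures.get(name)
            mesh_b = by_obs[b].structures.get(name)
            if mesh_a is None or mesh_b is None:
                row.update({m: np.nan for m in METRICS})
            else:
                vols = boolean_volumes(masks[a, name], masks[b, name])
                va, vb = vols["volA"], vols["volB"]
                row["dsc"] = (
                    2.0 * vols["volIntersection"] / (va + vb) if va + vb else np.nan
                )
                row["jsc"] = (
                    vols["volIntersection"] / vols["volUnion"]
                    if vols["volUnion"]
                    else np.nan
                )
                row.update(
                    distance_metrics(
                        mesh_a, mesh_b, resample_max_edge=resample_max_edge
                    )
                )
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Per-structure unweighted means over all (pair, patient) records.

    Returns one row per structure with the mean of each metric, the number
    of contributing records and the number of missing (undefined) records.
    """
    if records.empty:
        raise ValueError("no agreement records to aggregate")
    grouped = records.groupby("structure", sort=False)
    out = grouped[list(METRICS)].mean()
    out["n_records"] = grouped["dsc"].count()
    out["n_missing"] = grouped["dsc"].apply(lambda s: int(s.isna().sum()))
    return out.reset_index()
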