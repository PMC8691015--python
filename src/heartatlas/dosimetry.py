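"""Cumulative DVHs and the dose metrics DMEAN, D2CC and V5GY.

The cumulative dose-volume histogram records, for every 10 cGy dose
level, the absolute structure volume receiving at least that dose.  From
it (or directly from the grid) the pipeline derives

* DMEAN — volume-weighted mean dose (equal-volume voxels, so the plain
  mean over masked voxels),
* D2CC  — dose to the maximally exposed 2 cm^3, read off the cumulative
  DVH by linear interpolation (bin-floor variant available),
* V5GY  — relative volume receiving at least 5 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MM3_PER_CC, BinaryMask, GridSpec

__all__ = [
    "DoseGrid",
    "CumulativeDVH",
    "DoseMetrics",
    "cumulative_dvh",
    "dmean",
    "d2cc",
    "v5gy",
    "dvh_mean_dose",
    "dose_metrics",
]

DEFAULT_BIN_WIDTH = 0.10  # Gy (10 cGy)
V5_THRESHOLD = 5.0  # Gy
D2CC_VOLUME = 2.0  # cm^3


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a regular grid."""

    grid: GridSpec
    dose: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, float)
        if self.dose.shape != tuple(self.grid.shape):
            raise ValueError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose grid contains non-finite values")
        if self.dose.min() < 0:
            raise ValueError("dose must be non-negative")


@dataclass
class CumulativeDVH:
    """Absolute volume (cm^3) at-or-above each dose edge (Gy)."""

    structure: str
    bin_width: float
    edges: np.ndarray = field(repr=False)
    volume_cc: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        self.volume_cc = np.asarray(self.volume_cc, float)
        if self.edges.shape != self.volume_cc.shape:
            raise ValueError("edges and volume_cc must align")
        if np.any(np.diff(self.volume_cc) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    @property
    def total_volume_cc(self) -> float:
        return float(self.volume_cc[0])


@dataclass
class DoseMetrics:
    """DMEAN/D2CC/V5GY for one structure, with bookkeeping flags."""

    structure: str
    volume_cc: float
    dmean: float
    d2cc: float
    v5gy: float
    flags: tuple[str, ...] = ()


def _masked_doses(dose: DoseGrid, mask: BinaryMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise ValueError("dose grid and mask grid differ; no silent resampling")
    if mask.count == 0:
        raise ValueError("empty structure")
    return dose.dose[mask.values]


def cumulative_dvh(
    dose: DoseGrid,
    mask: BinaryMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
    structure: str = "",
) -> CumulativeDVH:
    """Cumulative DVH evaluated at every ``bin_width`` Gy edge from 0.

    volume_at_or_above(d) = voxel volume x #(masked voxels with dose >= d).
    The last edge exceeds the maximum structure dose, where the volume is 0.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    values = np.sort(_masked_doses(dose, mask))
    n_edges = int(np.floor(values[-1] / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    # count of doses >= edge, via sorted search
    counts = len(values) - np.searchsorted(values, edges, side="left")
    vol = counts * mask.grid.voxel_volume_mm3 / MM3_PER_CC
    return CumulativeDVH(structure, bin_width, edges, vol)


def dmean(dose: DoseGrid, mask: BinaryMask) -> float:
    """Volume-weighted mean dose (Gy) over the masked voxels."""
    return float(_masked_doses(dose, mask).mean())


def dvh_mean_dose(dvh: CumulativeDVH) -> float:
    """Mean dose recovered from the DVH: integral of V(d) dd / V(0).

    Agrees with the grid DMEAN to within one bin width.
    """
    if dvh.total_volume_cc == 0:
        raise ValueError("empty DVH")
    return float(np.trapezoid(dvh.volume_cc, dvh.edges)) / dvh.total_volume_cc


def d2cc(dvh: CumulativeDVH, interpolate: bool = True) -> tuple[float, bool]:
    """Dose to the maximally exposed 2 cm^3.

    Returns ``(dose_gy, small_volume_flag)``.  Structures below 2 cm^3 get
    their minimum dose and a raised flag instead of an error (small
    surrogate valves can legitimately drop below 2 cm^3).  With
    ``interpolate`` the crossing is linearly interpolated between DVH
    edges, otherwise the highest edge still covering 2 cm^3 is returned.
    """
    total = dvh.total_volume_cc
    if total == 0:
        raise ValueError("empty DVH")
    small = total < D2CC_VOLUME
    target = min(D2CC_VOLUME, total)
    vol = dvh.volume_cc
    # highest edge with vol >= target (vol non-increasing, vol[0] >= target)
    k = int(np.max(np.nonzero(vol >= target)[0]))
    if not interpolate or k + 1 >= len(vol) or vol[k] == target:
        return float(dvh.edges[k]), small
    drop = vol[k] - vol[k + 1]
    frac = (vol[k] - target) / drop if drop > 0 else 0.0
    return float(dvh.edges[k] + frac * dvh.bin_width), small


def v5gy(dvh: CumulativeDVH, threshold: float = V5_THRESHOLD) -> float:
    """Relative volume receiving at least ``threshold`` Gy, in [0, 1]."""
    if dvh.total_volume_cc == 0:
        raise ValueError("empty DVH")
    if threshold > dvh.edges[-1]:
        return 0.0
    k = int(np.searchsorted(dvh.edges, threshold, side="left"))
    return float(dvh.volume_cc[k]) / dvh.total_volume_cc


def dose_metrics(
    dose: DoseGrid,
    mask: BinaryMask,
    structure: str = "",
    bin_width: float = DEFAULT_BIN_WIDTH,
    interpolate: bool = True,
) -> DoseMetrics:
    """All three dose metrics for one structure from its DVH."""
    dvh = cumulative_dvh(dose, mask, bin_width=bin_width, structure=structure)
    d2, small = d2cc(dvh, interpolate=interpolate)
    flags = ("volume<2cc",) if small else ()
    return DoseMetrics(
        structure=structure,
        volume_cc=mask.volume_cc,
        dmean=dmean(dose, mask),
        d2cc=d2,
        v5gy=v5gy(dvh),
        flags=flags,
    )
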