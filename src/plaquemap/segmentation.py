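"""Dual-threshold segmentation of the lipid-rich necrotic core (LRNC).

Voxel classification follows the dual-threshold rule: within the vessel
wall, voxels with T2 strictly below the lower threshold are lipid-like core
(``lrnc_short``), voxels with T2 strictly above the upper threshold are
recent-hemorrhage core (``lrnc_iph``), and everything in between is
``other`` (fibrous wall).  Both kinds of core voxel count toward the lipid
area; hemorrhage covering more than 5% of the wall cross-section is flagged
as significant.  A single-threshold mode (lower threshold only) is provided
for the hemorrhage-free reanalysis.

Boundary voxels exactly at a threshold are non-core (strict inequalities).
Voxels whose fit failed are excluded from both numerator and denominator by
default (a config switch keeps them in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WallROI",
    "ThresholdPair",
    "SliceMeasurement",
    "PlaqueSummary",
    "classify_voxels",
    "measure_slice",
    "summarize_plaque",
    "filter_quality",
    "rasterize_contours",
    "CLASS_OUTSIDE",
    "CLASS_OTHER",
    "CLASS_LRNC_SHORT",
    "CLASS_LRNC_IPH",
    "CLASS_INVALID",
]

CLASS_OUTSIDE = 0
CLASS_OTHER = 1
CLASS_LRNC_SHORT = 2
CLASS_LRNC_IPH = 3
CLASS_INVALID = 4

CLASS_LABELS = {
    CLASS_OUTSIDE: "outside",
    CLASS_OTHER: "other",
    CLASS_LRNC_SHORT: "lrnc_short",
    CLASS_LRNC_IPH: "lrnc_iph",
    CLASS_INVALID: "invalid",
}


@dataclass
class WallROI:
    """Lumen and outer-wall masks defining the analyzable vessel wall."""

    lumen_mask: np.ndarray
    outer_mask: np.ndarray
    voxel_area: float = 0.04  # mm^2

    def __post_init__(self) -> None:
        self.lumen_mask = np.asarray(self.lumen_mask, dtype=bool)
        self.outer_mask = np.asarray(self.outer_mask, dtype=bool)
        if self.lumen_mask.shape != self.outer_mask.shape:
            raise ValueError("lumen and outer masks must share one shape")
        if np.any(self.lumen_mask & ~self.outer_mask):
            raise ValueError("lumen mask must lie inside the outer-wall mask")
        if self.voxel_area <= 0:
            raise ValueError("voxel_area must be positive")

    @property
    def wall_mask(self) -> np.ndarray:
        return self.outer_mask & ~self.lumen_mask

    @property
    def wall_area_mm2(self) -> float:
        return float(self.wall_mask.sum()) * self.voxel_area


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper T2 thresholds (ms) for the dual-threshold rule."""

    t2l: float
    t2h: float

    def __post_init__(self) -> None:
        if not self.t2l < self.t2h:
            raise ValueError("require t2l < t2h")


@dataclass
class SliceMeasurement:
    plaque_id: Optional[str]
    slice_index: int
    lipid_area_pct: float
    iph_area_pct: float
    wall_area_mm2: float
    significant_iph: bool
    histology_lipid_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.lipid_area_pct <= 100:
            raise ValueError("lipid_area_pct out of [0, 100]")
        if self.iph_area_pct > self.lipid_area_pct + 1e-9:
            raise ValueError("iph_area_pct cannot exceed lipid_area_pct")


@dataclass
class PlaqueSummary:
    plaque_id: str
    mean_lipid_area_pct: float
    volume_mm3: float
    n_slices: int
    symptomatic: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.volume_mm3 < 0 or self.n_slices < 1:
            raise ValueError("invalid plaque summary")


def classify_voxels(t2map, roi: WallROI, thresholds: ThresholdPair, mode: str = "dual") -> np.ndarray:
    """Classify wall voxels of a fitted T2 map.

    Returns an integer class map (see ``CLASS_*`` codes).  In ``dual`` mode
    core voxels are those with T2 < t2l (lipid) or T2 > t2h (hemorrhage);
    ``single_low`` ignores the upper threshold so long-T2 voxels stay
    ``other``.  Inequalities are strict; invalid-fit voxels are labelled
    separately so that area bookkeeping can exclude them.
    """
    if mode not in ("dual", "single_low"):
        raise ValueError("mode must be 'dual' or 'single_low'")
    t2 = np.asarray(t2map.t2, dtype=float)
    valid = np.asarray(t2map.valid, dtype=bool)
    wall = roi.wall_mask
    if t2.shape != wall.shape:
        raise ValueError("T2 map and ROI shapes differ")
    out = np.full(t2.shape, CLASS_OUTSIDE, dtype=np.uint8)
    out[wall] = CLASS_OTHER
    out[wall & ~valid] = CLASS_INVALID
    ok = wall & valid
    with np.errstate(invalid="ignore"):
        out[ok & (t2 < thresholds.t2l)] = CLASS_LRNC_SHORT
        if mode == "dual":
            out[ok & (t2 > thresholds.t2h)] = CLASS_LRNC_IPH
    return out


def measure_slice(
    class_map: np.ndarray,
    roi: WallROI,
    iph_significance_pct: float = 5.0,
    plaque_id: Optional[str] = None,
    slice_index: int = 0,
    histology_lipid_pct: Optional[float] = None,
    include_invalid_in_denominator: bool = False,
) -> SliceMeasurement:
    """Quantify one classified slice.

    Lipid area is the core voxel count (both classes) as a percentage of the
    wall voxel count; hemorrhage covering strictly more than
    ``iph_significance_pct`` of the wall is flagged significant.  The wall
    denominator excludes invalid-fit voxels unless
    ``include_invalid_in_denominator`` is set; the physical wall area in
    mm^2 always counts every wall voxel.
    """
    class_map = np.asarray(class_map)
    wall = roi.wall_mask
    if class_map.shape != wall.shape:
        raise ValueError("class map and ROI shapes differ")
    n_wall = int(wall.sum())
    if n_wall == 0:
        raise ValueError("empty wall: nothing to measure")
    n_invalid = int((class_map == CLASS_INVALID).sum())
    denom = n_wall if include_invalid_in_denominator else n_wall - n_invalid
    if denom <= 0:
        raise ValueError("no valid wall voxels to measure")
    n_short = int((class_map == CLASS_LRNC_SHORT).sum())
    n_iph = int((class_map == CLASS_LRNC_IPH).sum())
    lipid_pct = 100.0 * (n_short + n_iph) / denom
    iph_pct = 100.0 * n_iph / denom
    return SliceMeasurement(
        plaque_id=plaque_id,
        slice_index=slice_index,
        lipid_area_pct=lipid_pct,
        iph_area_pct=iph_pct,
        wall_area_mm2=n_wall * roi.voxel_area,
        significant_iph=iph_pct > iph_significance_pct,
        histology_lipid_pct=histology_lipid_pct,
    )


def summarize_plaque(
    slices: Sequence[SliceMeasurement],
    slice_thickness: float,
    symptomatic: Optional[bool] = None,
    area_weighted: bool = False,
) -> PlaqueSummary:
    """Aggregate slice measurements of one plaque.

    The per-plaque lipid percentage is the unweighted mean of slice values
    by default (an area-weighted mean is available); plaque volume is the
    sum of wall areas times slice thickness.
    """
    if not slices:
        raise ValueError("need at least one slice")
    pids = {s.plaque_id for s in slices}
    if len(pids) != 1:
        raise ValueError(f"mixed plaque_ids in one summary: {sorted(map(str, pids))}")
    vals = np.array([s.lipid_area_pct for s in slices])
    areas = np.array([s.wall_area_mm2 for s in slices])
    mean = float(np.average(vals, weights=areas)) if area_weighted else float(vals.mean())
    return PlaqueSummary(
        plaque_id=slices[0].plaque_id,
        mean_lipid_area_pct=mean,
        volume_mm3=float(areas.sum() * slice_thickness),
        n_slices=len(slices),
        symptomatic=symptomatic,
    )


def filter_quality(records, min_quality: int = 3, column: str = "quality"):
    """Apply the image-quality exclusion rule (keep scores >= min_quality).

    ``records`` may be a DataFrame with a quality column or a sequence of
    objects with a ``quality`` attribute.  Returns ``(retained, n_excluded)``.
    """
    if isinstance(records, pd.DataFrame):
        scores = records[column].to_numpy()
    else:
        records = list(records)
        scores = np.array([getattr(r, "quality") for r in records])
    if scores.size and (scores.min() < 1 or scores.max() > 5):
        raise ValueError("quality scores must lie in 1-5")
    keep = scores >= min_quality
    n_excluded = int((~keep).sum())
    if isinstance(records, pd.DataFrame):
        return records.loc[keep].reset_index(drop=True), n_excluded
    return [r for r, k in zip(records, keep) if k], n_excluded


def rasterize_contours(
    lumen_xy: np.ndarray,
    outer_xy: np.ndarray,
    shape: tuple[int, int],
    voxel_area: float = 0.04,
) -> WallROI:
    """Rasterize lumen/outer polygon contours to a :class:`WallROI`.

    A voxel belongs to a polygon when its centre falls inside it (even-odd
    rule for simple, non-self-intersecting contours).  Contours are arrays
    of (x, y) vertices in voxel coordinates.
    """
    from matplotlib.path import Path

    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    lumen = Path(np.asarray(lumen_xy)).contains_points(pts).reshape(shape)
    outer = Path(np.asarray(outer_xy)).contains_points(pts).reshape(shape)
    return WallROI(lumen_mask=lumen & outer, outer_mask=outer, voxel_area=voxel_area)
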