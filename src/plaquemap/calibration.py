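"""Threshold calibration against histology by exhaustive grid search.

For every candidate pair (lower, upper) on a regular grid, the slice-level
lipid area is recomputed from the fitted T2 values and correlated (Pearson)
against the histological lipid area.  The winning pair maximizes R; ties
are broken deterministically by lower RMSE, then lower t2l, then lower t2h.
Out-of-sample performance is estimated by leave-one-out cross-validation:
each slice is predicted with the pair calibrated on the remaining slices.

The grid evaluation is exact and fast: per slice, the lipid percentage at a
pair is a function only of how many wall T2 values fall strictly below t2l
and strictly above t2h, so one sorted pass per slice yields the whole
surface via ``searchsorted``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import stats as cstats
from .segmentation import ThresholdPair

__all__ = [
    "CalibrationGrid",
    "CalibrationSlice",
    "CalibrationResult",
    "ModeComparison",
    "ThresholdCalibrator",
    "ZeroVarianceError",
    "grid_search",
    "loocv",
    "compare_modes",
]


class ZeroVarianceError(ValueError):
    """Raised when a correlation input has no variance."""


@dataclass(frozen=True)
class CalibrationGrid:
    """Regular (t2l, t2h) search grid in ms."""

    t2l_min: float = 30.0
    t2l_max: float = 50.0
    t2h_min: float = 70.0
    t2h_max: float = 120.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.t2l_min > self.t2l_max or self.t2h_min > self.t2h_max:
            raise ValueError("ranges must satisfy min <= max")
        if self.t2l_max >= self.t2h_min:
            raise ValueError("t2l range must lie entirely below t2h range")

    @property
    def t2l_values(self) -> np.ndarray:
        return np.arange(self.t2l_min, self.t2l_max + self.step / 2, self.step)

    @property
    def t2h_values(self) -> np.ndarray:
        return np.arange(self.t2h_min, self.t2h_max + self.step / 2, self.step)


@dataclass
class CalibrationSlice:
    """Per-slice calibration datum: wall T2 values and histology pairing.

    ``n_wall`` is the denominator used for lipid percentages.  It defaults
    to the number of valid T2 values, but :meth:`from_t2map` passes the full
    wall voxel count so that voxels without a usable fit (for example
    calcium signal voids) still contribute wall area, matching the
    convention of histological area percentages.
    """

    t2_values: np.ndarray
    histology_pct: float
    plaque_id: Optional[str] = None
    slice_index: int = 0
    iph_core_share: Optional[float] = None
    n_wall: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.t2_values, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("slice has no valid wall T2 values")
        self.t2_values = np.sort(v)
        if self.n_wall is None:
            self.n_wall = int(self.t2_values.size)
        elif self.n_wall < self.t2_values.size:
            raise ValueError("n_wall cannot be smaller than the number of T2 values")

    @classmethod
    def from_t2map(cls, t2map, roi, histology_pct, plaque_id=None, slice_index=0,
                   iph_core_share=None) -> "CalibrationSlice":
        wall = roi.wall_mask
        sel = wall & np.asarray(t2map.valid, dtype=bool)
        return cls(
            t2_values=np.asarray(t2map.t2)[sel],
            histology_pct=float(histology_pct),
            plaque_id=plaque_id,
            slice_index=slice_index,
            iph_core_share=iph_core_share,
            n_wall=int(wall.sum()),
        )


def _coerce_slices(slices) -> list[CalibrationSlice]:
    out = []
    for s in slices:
        if isinstance(s, CalibrationSlice):
            out.append(s)
        else:  # (t2map, roi, histology %) tuple per the pipeline contract
            t2map, roi, hist = s
            out.append(CalibrationSlice.from_t2map(t2map, roi, hist))
    return out


def _lipid_surface(slices: Sequence[CalibrationSlice], grid: CalibrationGrid,
                   mode: str) -> np.ndarray:
    """Lipid % per (slice, t2l, t2h) grid point, shape (n, L, H)."""
    t2l = grid.t2l_values
    t2h = grid.t2h_values
    n = len(slices)
    m = np.empty((n, t2l.size, t2h.size))
    for i, s in enumerate(slices):
        v = s.t2_values  # sorted
        denom = float(s.n_wall)
        below = np.searchsorted(v, t2l, side="left")          # strictly < t2l
        above = v.size - np.searchsorted(v, t2h, side="right")  # strictly > t2h
        if mode == "single_low":
            m[i] = (100.0 / denom) * below[:, None] * np.ones((1, t2h.size))
        else:
            m[i] = (100.0 / denom) * (below[:, None] + above[None, :])
    return m


def _pearson_columns(m2: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each column of m2 (n, P) and y (n,); NaN where a
    column is degenerate."""
    yc = y - y.mean()
    sy = np.sqrt((yc * yc).sum())
    mc = m2 - m2.mean(axis=0, keepdims=True)
    sm = np.sqrt((mc * mc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc * yc[:, None]).sum(axis=0) / (sm * sy)
    r[sm == 0] = np.nan
    return r


def _best_pair(m: np.ndarray, y: np.ndarray, grid: CalibrationGrid):
    """Return (il, ih, r, rmse, r_surface) with deterministic tie-breaking."""
    n, L, H = m.shape
    m2 = m.reshape(n, L * H)
    r = _pearson_columns(m2, y)
    if np.all(np.isnan(r)):
        raise ZeroVarianceError("measured lipid values have zero variance at every grid pair")
    rmax = np.nanmax(r)
    cand = np.flatnonzero(np.isfinite(r) & (r >= rmax - 1e-12))
    diffs = m2[:, cand] - y[:, None]
    rmse = np.sqrt((diffs * diffs).mean(axis=0))
    il, ih = np.unravel_index(cand, (L, H))
    # ties: min RMSE, then lowest t2l, then lowest t2h
    order = np.lexsort((ih, il, np.round(rmse, 12)))
    best = order[0]
    return int(il[best]), int(ih[best]), float(r[cand[best]]), float(rmse[best]), \
        r.reshape(L, H)


@dataclass
class CalibrationResult:
    """Results of threshold calibration (optionally with LOOCV fields)."""

    best_pair: ThresholdPair
    best_r: float
    best_p: float
    rmse_pct: float
    grid_scores: np.ndarray  # Pearson R surface, shape (L, H)
    t2l_values: np.ndarray
    t2h_values: np.ndarray
    mode: str
    n_slices: int
    loocv_r: Optional[float] = None
    loocv_p: Optional[float] = None
    loocv_predictions: Optional[np.ndarray] = None

    def summary(self) -> str:
        lines = [
            "Threshold calibration (grid search vs histology)",
            "================================================",
            f"mode                : {self.mode}",
            f"slices              : {self.n_slices}",
            f"grid                : t2l {self.t2l_values[0]:g}-{self.t2l_values[-1]:g} ms, "
            f"t2h {self.t2h_values[0]:g}-{self.t2h_values[-1]:g} ms",
            f"best thresholds     : ({self.best_pair.t2l:g}, {self.best_pair.t2h:g}) ms",
            f"in-sample Pearson R : {self.best_r:.4f} (p = {self.best_p:.2e})",
            f"RMSE at best pair   : {self.rmse_pct:.2f} %",
        ]
        if self.loocv_r is not None:
            lines.append(f"leave-one-out R     : {self.loocv_r:.4f} (p = {self.loocv_p:.2e})")
        return "\n".join(lines)


def _check_histology(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError("histology values must be finite")
    if np.std(y) == 0:
        raise ZeroVarianceError("histology values have zero variance")


def grid_search(slices, grid: Optional[CalibrationGrid] = None,
                mode: str = "dual") -> CalibrationResult:
    """Exhaustive search for the threshold pair maximizing Pearson R."""
    grid = grid or CalibrationGrid()
    sl = _coerce_slices(slices)
    if len(sl) < 3:
        raise ValueError("grid search needs at least 3 slices")
    y = np.array([s.histology_pct for s in sl], dtype=float)
    _check_histology(y)
    m = _lipid_surface(sl, grid, mode)
    il, ih, r, rmse, surface = _best_pair(m, y, grid)
    t2l = float(grid.t2l_values[il])
    t2h = float(grid.t2h_values[ih])
    p = cstats.pearson_r(m[:, il, ih], y).p if np.std(m[:, il, ih]) > 0 else float("nan")
    return CalibrationResult(
        best_pair=ThresholdPair(t2l, t2h),
        best_r=r,
        best_p=p,
        rmse_pct=rmse,
        grid_scores=surface,
        t2l_values=grid.t2l_values,
        t2h_values=grid.t2h_values,
        mode=mode,
        n_slices=len(sl),
    )


def loocv(slices, grid: Optional[CalibrationGrid] = None,
          mode: str = "dual") -> tuple[float, float, np.ndarray]:
    """Leave-one-out cross-validated calibration.

    For each slice the grid search runs on the remaining slices and the
    winning pair is applied to the held-out slice.  Returns
    ``(loocv_r, loocv_p, predictions)`` where predictions are per-slice
    held-out lipid percentages in input order.
    """
    grid = grid or CalibrationGrid()
    sl = _coerce_slices(slices)
    n = len(sl)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 slices")
    y = np.array([s.histology_pct for s in sl], dtype=float)
    _check_histology(y)
    m = _lipid_surface(sl, grid, mode)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yi = y[mask]
        if np.std(yi) == 0:
            raise ZeroVarianceError(
                "histology values have zero variance in a leave-one-out training fold")
        il, ih, _, _, _ = _best_pair(m[mask], yi, grid)
        preds[i] = m[i, il, ih]
        mask[i] = True
    res = cstats.pearson_r(preds, y)
    return res.r, res.p, preds


@dataclass
class ModeComparison:
    """Dual- vs single-threshold calibration, with heavy-hemorrhage subset."""

    dual_r: float
    single_low_r: float
    dual_best_pair: ThresholdPair
    single_low_t2l: float
    subset_definition: str
    n_slices: int
    n_excluded: int
    dual_r_excl: Optional[float] = None
    single_low_r_excl: Optional[float] = None


def compare_modes(slices, grid: Optional[CalibrationGrid] = None,
                  heavy_iph_share: float = 0.5) -> ModeComparison:
    """Compare dual- and single-threshold calibration.

    Slices whose hemorrhage occupies more than ``heavy_iph_share`` of the
    necrotic core (annotation carried by the slices, from ground truth or
    measurement) define the heavy-hemorrhage subset; the comparison is
    repeated with that subset excluded.
    """
    grid = grid or CalibrationGrid()
    sl = _coerce_slices(slices)
    dual = grid_search(sl, grid, mode="dual")
    single = grid_search(sl, grid, mode="single_low")
    shares = np.array([s.iph_core_share if s.iph_core_share is not None else 0.0
                       for s in sl])
    keep = shares <= heavy_iph_share
    n_excluded = int((~keep).sum())
    dual_ex = single_ex = None
    if n_excluded and keep.sum() >= 3:
        subset = [s for s, k in zip(sl, keep) if k]
        try:
            dual_ex = grid_search(subset, grid, mode="dual").best_r
            single_ex = grid_search(subset, grid, mode="single_low").best_r
        except ZeroVarianceError:
            pass
    return ModeComparison(
        dual_r=dual.best_r,
        single_low_r=single.best_r,
        dual_best_pair=dual.best_pair,
        single_low_t2l=single.best_pair.t2l,
        subset_definition=(
            f"slices with hemorrhage infiltrating > {heavy_iph_share:.0%} of the core excluded"
        ),
        n_slices=len(sl),
        n_excluded=n_excluded,
        dual_r_excl=dual_ex,
        single_low_r_excl=single_ex,
    )


class ThresholdCalibrator:
    """Model object: calibrate segmentation thresholds against histology.

    Parameters
    ----------
    slices : sequence of CalibrationSlice or (T2Map, WallROI, histology %) tuples
    grid : CalibrationGrid
    mode : 'dual' or 'single_low'
    """

    def __init__(self, slices, grid: Optional[CalibrationGrid] = None, mode: str = "dual"):
        self.slices = _coerce_slices(slices)
        self.grid = grid or CalibrationGrid()
        self.mode = mode

    def fit(self, run_loocv: bool = True) -> CalibrationResult:
        res = grid_search(self.slices, self.grid, self.mode)
        if run_loocv:
            r, p, preds = loocv(self.slices, self.grid, self.mode)
            res.loocv_r, res.loocv_p, res.loocv_predictions = r, p, preds
        return res
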