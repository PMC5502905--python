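"""Voxel-wise T2 relaxometry from multi-echo spin-echo magnitude images.

The signal model is the monoexponential decay of transverse magnetization,

    S(TE) = S0 * exp(-TE / T2)            (optionally + C),

fitted per voxel by nonlinear least squares on the untransformed magnitudes.
A log-linear least-squares solution initializes the nonlinear fit; the
optimizer is a damped Gauss-Newton (Levenberg-Marquardt) iteration vectorized
over voxels, so whole slices fit in milliseconds.

The public surface follows the Model/Results convention: build a
:class:`T2Relaxometry` model from an :class:`EchoSeries` (and optionally a
wall ROI), call :meth:`~T2Relaxometry.fit`, and read the parameter maps off
the returned :class:`T2MapResult`.  The functions :func:`fit_voxel` and
:func:`fit_slice` expose the same engine for scripting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "EchoSeries",
    "FitOptions",
    "T2Map",
    "T2MapResult",
    "T2Relaxometry",
    "VoxelFit",
    "fit_voxel",
    "fit_slice",
    "loglinear_fit",
    "REASON_LABELS",
]

# Per-voxel fit status codes (stored in T2Map.reason).
REASON_OK = 0
REASON_NO_SIGNAL = 1
REASON_AT_BOUND = 2
REASON_NOT_CONVERGED = 3
REASON_OUTSIDE_ROI = 4
REASON_LOW_QUALITY = 5

REASON_LABELS = {
    REASON_OK: "ok",
    REASON_NO_SIGNAL: "no_signal",
    REASON_AT_BOUND: "bound",
    REASON_NOT_CONVERGED: "not_converged",
    REASON_OUTSIDE_ROI: "outside_roi",
    REASON_LOW_QUALITY: "low_quality",
}


@dataclass(frozen=True)
class FitOptions:
    """Options for the monoexponential fit.

    t2_min, t2_max : ms
        Hard bounds on T2.  A fit that pins at a bound is flagged invalid
        (reason ``bound``) but the pinned value is still reported, so that
        downstream segmentation can decide its fate.
    rtol_sse : float
        Convergence tolerance on the relative change of the sum of squared
        residuals between accepted iterations.
    max_iter : int
        Iteration cap for the damped Gauss-Newton loop.
    offset : bool
        If True, fit a three-parameter model ``S0*exp(-TE/T2) + C``.
        Off by default: the two-parameter model is the standard choice for
        fat-suppressed multi-echo spin echo.
    min_rsq : float or None
        Optional goodness-of-fit floor.  Voxels with R^2 below it are flagged
        invalid (reason ``low_quality``).  Off (None) by default.
    """

    t2_min: float = 1.0
    t2_max: float = 1000.0
    rtol_sse: float = 1e-8
    max_iter: int = 200
    offset: bool = False
    min_rsq: Optional[float] = None


@dataclass
class EchoSeries:
    """One slice of a multi-echo acquisition.

    data : ndarray, shape (n_echoes, ny, nx)
        Magnitude images, one per echo, arbitrary signal units, non-negative.
    echo_times : ndarray, shape (n_echoes,)
        Echo times in ms, strictly increasing.
    """

    data: np.ndarray
    echo_times: np.ndarray
    slice_index: int = 0
    voxel_area: float = 0.04  # mm^2
    slice_thickness: float = 2.0  # mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_echoes, ny, nx)")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.data.shape[0]:
            raise ValueError("echo_times length must match the echo axis of data")
        if self.echo_times.size < 3:
            raise ValueError("at least 3 echoes are required")
        if not np.all(np.diff(self.echo_times) > 0):
            raise ValueError("echo_times must be strictly increasing")
        if np.any(self.echo_times <= 0):
            raise ValueError("echo_times must be positive")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


class VoxelFit(NamedTuple):
    t2: float
    s0: float
    rsq: float
    valid: bool
    reason: str
    offset: float = 0.0


@dataclass
class T2Map:
    """Per-voxel parameter maps for one slice."""

    t2: np.ndarray
    s0: np.ndarray
    rsq: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    offset: Optional[np.ndarray] = None
    slice_index: int = 0
    voxel_area: float = 0.04
    slice_thickness: float = 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.t2.shape

    def reason_label(self, idx: tuple[int, int]) -> str:
        return REASON_LABELS[int(self.reason[idx])]


def loglinear_fit(signal: np.ndarray, echo_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear least-squares estimate of (t2, s0), vectorized over voxels.

    Zero/negative samples are excluded from the log.  Exact when the data are
    noiseless monoexponential with positive amplitude.  Voxels with fewer
    than two positive samples, or a non-decaying slope, get NaN.
    """
    y = np.atleast_2d(np.asarray(signal, dtype=float))
    te = np.asarray(echo_times, dtype=float)
    pos = y > 0
    w = pos.astype(float)
    ly = np.where(pos, np.log(np.where(pos, y, 1.0)), 0.0)
    sw = w.sum(axis=1)
    sx = (w * te).sum(axis=1)
    sy = ly.sum(axis=1)
    sxx = (w * te * te).sum(axis=1)
    sxy = (ly * te).sum(axis=1)
    denom = sw * sxx - sx * sx
    ok = (sw >= 2) & (denom > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, (sw * sxy - sx * sy) / np.where(ok, denom, 1.0), np.nan)
        inter = np.where(ok, (sy - slope * sx) / np.where(sw > 0, sw, 1.0), np.nan)
    decaying = ok & (slope < 0)
    t2 = np.where(decaying, -1.0 / np.where(decaying, slope, -1.0), np.nan)
    s0 = np.where(ok, np.exp(np.clip(inter, -700, 700)), np.nan)
    return t2, s0


def _model(params: np.ndarray, te: np.ndarray, offset: bool) -> np.ndarray:
    s0 = params[:, 0:1]
    t2 = params[:, 1:2]
    m = s0 * np.exp(-te[None, :] / t2)
    if offset:
        m = m + params[:, 2:3]
    return m


def _jacobian(params: np.ndarray, te: np.ndarray, offset: bool) -> np.ndarray:
    s0 = params[:, 0:1]
    t2 = params[:, 1:2]
    w = np.exp(-te[None, :] / t2)
    n, e = w.shape
    p = 3 if offset else 2
    jac = np.empty((n, e, p))
    jac[:, :, 0] = w
    jac[:, :, 1] = s0 * w * te[None, :] / (t2 * t2)
    if offset:
        jac[:, :, 2] = 1.0
    return jac


def _fit_batch(y: np.ndarray, te: np.ndarray, options: FitOptions):
    """Damped Gauss-Newton monoexponential fit, vectorized over voxels.

    Parameters
    ----------
    y : ndarray, shape (n_voxels, n_echoes)

    Returns
    -------
    t2, s0, rsq, valid, reason[, offset] arrays of length n_voxels.
    """
    y = np.asarray(y, dtype=float)
    n, e = y.shape
    opts = options
    p = 3 if opts.offset else 2

    t2 = np.full(n, np.nan)
    s0 = np.full(n, np.nan)
    off = np.zeros(n)
    rsq = np.zeros(n)
    reason = np.full(n, REASON_OK, dtype=np.uint8)

    finite = np.isfinite(y).all(axis=1)
    has_signal = finite & (np.nanmax(np.where(finite[:, None], y, 0.0), axis=1) > 0)
    reason[~has_signal] = REASON_NO_SIGNAL
    idx = np.flatnonzero(has_signal)
    if idx.size == 0:
        valid = np.zeros(n, dtype=bool)
        out = (t2, s0, rsq, valid, reason)
        return out + ((off,) if opts.offset else ())

    yy = y[idx]
    t2_0, s0_0 = loglinear_fit(yy, te)
    # Fallbacks for voxels where the log-linear estimate failed.
    mid = float(np.median(te))
    t2_0 = np.where(np.isfinite(t2_0), t2_0, mid)
    s0_0 = np.where(np.isfinite(s0_0) & (s0_0 > 0), s0_0, np.maximum(yy.max(axis=1), 1e-12))
    t2_0 = np.clip(t2_0, opts.t2_min, opts.t2_max)

    params = np.zeros((idx.size, p))
    params[:, 0] = s0_0
    params[:, 1] = t2_0

    f = _model(params, te, opts.offset) - yy
    sse = np.einsum("ij,ij->i", f, f)
    lam = np.full(idx.size, 1e-3)
    converged = sse <= 1e-28
    active = ~converged

    for _ in range(opts.max_iter):
        act = np.flatnonzero(active)
        if act.size == 0:
            break
        pa = params[act]
        fa = _model(pa, te, opts.offset) - yy[act]
        jac = _jacobian(pa, te, opts.offset)
        g = np.einsum("kep,ke->kp", jac, fa)
        hess = np.einsum("kep,keq->kpq", jac, jac)
        diag = np.einsum("kpp->kp", hess).copy()
        diag = np.maximum(diag, 1e-12)
        aa = hess + lam[act, None, None] * diag[:, :, None] * np.eye(p)[None, :, :]
        try:
            delta = -np.linalg.solve(aa, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by damping
            delta = -g / np.maximum(diag, 1e-12)
        cand = pa + delta
        cand[:, 0] = np.maximum(cand[:, 0], 0.0)
        cand[:, 1] = np.clip(cand[:, 1], opts.t2_min, opts.t2_max)
        fc = _model(cand, te, opts.offset) - yy[act]
        sse_new = np.einsum("ij,ij->i", fc, fc)
        sse_old = sse[act]
        better = sse_new < sse_old
        # Accept improving steps, tighten damping; inflate damping otherwise.
        upd = act[better]
        params[upd] = cand[better]
        sse[upd] = sse_new[better]
        lam[upd] = np.maximum(lam[upd] / 3.0, 1e-12)
        rej = act[~better]
        lam[rej] *= 4.0
        # Convergence: tiny relative improvement on an accepted step, or
        # damping blown up so far that no progress is possible.
        rel = (sse_old[better] - sse_new[better]) / np.maximum(sse_old[better], 1e-300)
        conv_now = upd[rel <= opts.rtol_sse]
        converged[conv_now] = True
        converged[act[lam[act] > 1e10]] = True
        active = ~converged

    t2_fit = params[:, 1]
    s0_fit = params[:, 0]
    tss = np.einsum("ij,ij->i", yy - yy.mean(axis=1, keepdims=True),
                    yy - yy.mean(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - sse / np.where(tss > 0, tss, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    sub_reason = np.full(idx.size, REASON_OK, dtype=np.uint8)
    eps = 1e-9
    at_bound = (t2_fit <= opts.t2_min * (1 + eps)) | (t2_fit >= opts.t2_max * (1 - eps))
    sub_reason[at_bound] = REASON_AT_BOUND
    not_conv = ~converged & ~at_bound
    sub_reason[not_conv] = REASON_NOT_CONVERGED
    if opts.min_rsq is not None:
        low = (sub_reason == REASON_OK) & (r2 < opts.min_rsq)
        sub_reason[low] = REASON_LOW_QUALITY

    t2[idx] = t2_fit
    s0[idx] = s0_fit
    rsq[idx] = r2
    reason[idx] = sub_reason
    if opts.offset:
        off[idx] = params[:, 2]
    valid = reason == REASON_OK
    out = (t2, s0, rsq, valid, reason)
    return out + ((off,) if opts.offset else ())


def fit_voxel(signal, echo_times, options: Optional[FitOptions] = None) -> VoxelFit:
    """Fit the monoexponential model to one voxel's echo train."""
    opts = options or FitOptions()
    signal = np.asarray(signal, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    if signal.shape != echo_times.shape:
        raise ValueError("signal and echo_times must have equal length")
    if signal.size < 3:
        raise ValueError("at least 3 echoes are required")
    res = _fit_batch(signal[None, :], echo_times, opts)
    t2, s0, rsq, valid, reason = res[:5]
    off = float(res[5][0]) if opts.offset else 0.0
    return VoxelFit(
        t2=float(t2[0]),
        s0=float(s0[0]),
        rsq=float(rsq[0]),
        valid=bool(valid[0]),
        reason=REASON_LABELS[int(reason[0])],
        offset=off,
    )


def fit_slice(series: EchoSeries, roi=None, options: Optional[FitOptions] = None) -> T2Map:
    """Fit every voxel inside the outer-wall mask of ``roi``.

    Voxels outside the mask are left invalid with reason ``outside_roi``.
    ``roi`` may be a WallROI (its ``outer_mask`` is used), a boolean mask
    array, or None to fit the full grid.  The result is deterministic for
    fixed input.
    """
    opts = options or FitOptions()
    ny, nx = series.shape
    if roi is None:
        mask = np.ones((ny, nx), dtype=bool)
    elif hasattr(roi, "outer_mask"):
        mask = np.asarray(roi.outer_mask, dtype=bool)
    else:
        mask = np.asarray(roi, dtype=bool)
    if mask.shape != (ny, nx):
        raise ValueError("ROI shape does not match the image grid")
    if not mask.any():
        raise ValueError("ROI is empty: no voxels to fit")

    flat = series.data.reshape(series.n_echoes, -1).T  # (n_voxels, n_echoes)
    sel = mask.ravel()
    res = _fit_batch(flat[sel], series.echo_times, opts)
    t2v, s0v, rsqv, validv, reasonv = res[:5]

    t2 = np.full(ny * nx, np.nan)
    s0 = np.full(ny * nx, np.nan)
    rsq = np.zeros(ny * nx)
    valid = np.zeros(ny * nx, dtype=bool)
    reason = np.full(ny * nx, REASON_OUTSIDE_ROI, dtype=np.uint8)
    t2[sel], s0[sel], rsq[sel], valid[sel], reason[sel] = t2v, s0v, rsqv, validv, reasonv
    offset = None
    if opts.offset:
        offset = np.zeros(ny * nx)
        offset[sel] = res[5]
        offset = offset.reshape(ny, nx)
    return T2Map(
        t2=t2.reshape(ny, nx),
        s0=s0.reshape(ny, nx),
        rsq=rsq.reshape(ny, nx),
        valid=valid.reshape(ny, nx),
        reason=reason.reshape(ny, nx),
        offset=offset,
        slice_index=series.slice_index,
        voxel_area=series.voxel_area,
        slice_thickness=series.slice_thickness,
    )


@dataclass
class T2MapResult:
    """Results object wrapping a fitted :class:`T2Map`."""

    t2map: T2Map
    options: FitOptions
    n_fitted: int

    def __getattr__(self, name):
        return getattr(self.t2map, name)

    def summary(self) -> str:
        m = self.t2map
        v = m.valid
        lines = [
            "T2 relaxometry fit",
            "==================",
            f"grid                : {m.shape[0]} x {m.shape[1]}",
            f"voxels fitted       : {self.n_fitted}",
            f"voxels valid        : {int(v.sum())}",
        ]
        if v.any():
            lines += [
                f"median T2 (ms)      : {np.median(m.t2[v]):.2f}",
                f"IQR T2 (ms)         : "
                f"{np.percentile(m.t2[v], 25):.2f} - {np.percentile(m.t2[v], 75):.2f}",
                f"median R^2          : {np.median(m.rsq[v]):.4f}",
            ]
        counts = {}
        for code, label in REASON_LABELS.items():
            c = int((m.reason == code).sum())
            if c and code != REASON_OUTSIDE_ROI:
                counts[label] = c
        lines.append(f"status counts       : {counts}")
        return "\n".join(lines)


class T2Relaxometry:
    """Monoexponential T2 relaxometry model for one echo series.

    Parameters
    ----------
    series : EchoSeries
    roi : WallROI, mask array or None
        Restricts fitting to the outer-wall mask when given.
    options : FitOptions
    """

    def __init__(self, series: EchoSeries, roi=None, options: Optional[FitOptions] = None):
        self.series = series
        self.roi = roi
        self.options = options or FitOptions()

    def fit(self) -> T2MapResult:
        t2map = fit_slice(self.series, self.roi, self.options)
        n_fitted = int((t2map.reason != REASON_OUTSIDE_ROI).sum())
        return T2MapResult(t2map=t2map, options=self.options, n_fitted=n_fitted)
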