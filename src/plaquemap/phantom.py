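"""Synthetic carotid plaque phantoms for multi-echo T2 mapping.

Generates, from a seeded configuration, everything the analysis pipeline
consumes: per-slice multi-echo image stacks with Rician (or Gaussian) noise,
vessel-wall ROIs, histology-style lipid-area ground truth with measurement
jitter, two clinical cohorts with different mean lipid fractions, and
scan-rescan replicate pairs.

The phantom geometry is a circular annulus (vessel wall) around a lumen.
Plaque components occupy contiguous angular wedges of the wall:

* lipid core          - short T2 (below the lower segmentation threshold),
* fibrous wall        - intermediate T2,
* recent hemorrhage   - long T2 (above the upper threshold), placed spatially
  inside the lipid wedge (hemorrhage is structurally part of the core),
* calcium             - signal void (near-zero proton density), in a separate
  wedge, with its mask emitted for plaque-type classification.

Per-voxel true T2 values are drawn from truncated normal distributions whose
truncation bounds keep the component classes separable by the 42/90 ms
threshold pair, so that threshold calibration against the emulated histology
can recover that pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .relaxometry import EchoSeries
from .segmentation import WallROI

__all__ = [
    "PhantomConfig",
    "CohortSpec",
    "HistologyEmulation",
    "TissueMap",
    "SliceData",
    "PlaqueData",
    "LABELS",
    "LABEL_CODES",
    "make_tissue_map",
    "simulate_echo_series",
    "make_cohort",
    "make_rescan_pair",
    "wall_roi_from_config",
]

# Tissue label codes.
LABELS = {0: "background", 1: "lumen", 2: "wall_fibrous", 3: "lipid", 4: "iph", 5: "calcium"}
LABEL_CODES = {v: k for k, v in LABELS.items()}

# Component T2 distributions: class -> (mean ms, sd ms).  Truncation bounds
# (class -> (low, high)) keep lipid strictly below and hemorrhage strictly
# above the 42/90 ms generating thresholds, with guard bands sized so that
# fit noise at the default SNR blurs each boundary roughly symmetrically.
DEFAULT_COMPONENT_T2 = {
    "lipid": (36.0, 4.0),
    "wall_fibrous": (60.0, 10.0),
    "iph": (94.0, 1.5),
    "lumen": (150.0, 30.0),
}
DEFAULT_T2_BOUNDS = {
    "lipid": (15.0, 41.0),
    "wall_fibrous": (42.0, 90.0),
    "iph": (92.0, 160.0),
    "lumen": (80.0, 250.0),
}
# Between-slice (subject) variation of each component's mean T2, in ms.
# Real vessel wall relaxation varies between patients; without this the
# fibrous fraction of every slice would be a deterministic complement of the
# core fraction and threshold calibration would lose its cost structure
# (Pearson correlation is blind to any misclassification that is an affine
# function of the core fraction).
DEFAULT_T2_SLICE_SD = {
    "lipid": 3.0,
    "wall_fibrous": 12.0,
    "iph": 0.5,
    "lumen": 0.0,
}
# Proton-density signal per class; lumen is black-blood suppressed and
# calcium is a signal void.
DEFAULT_COMPONENT_S0 = {
    "background": 0.0,
    "lumen": 8.0,
    "wall_fibrous": 100.0,
    "lipid": 100.0,
    "iph": 100.0,
    "calcium": 2.0,
}


def _default_echo_times() -> tuple[float, ...]:
    return tuple(np.linspace(9.0, 127.0, 14))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, acquisition and noise settings for the synthetic scanner.

    Lengths are voxels unless noted.  ``voxel_size`` is the in-plane voxel
    edge in mm (0.2 mm default, giving a wall area of ~28 mm^2 with the
    default annulus, i.e. a realistic endarterectomy-scale plaque).
    """

    image_size: int = 64
    slice_thickness: float = 2.0  # mm
    voxel_size: float = 0.2  # mm
    echo_times: tuple = field(default_factory=_default_echo_times)
    lumen_radius: float = 6.0
    outer_radius: float = 16.0
    component_t2: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENT_T2))
    component_t2_bounds: dict = field(default_factory=lambda: dict(DEFAULT_T2_BOUNDS))
    component_t2_slice_sd: dict = field(default_factory=lambda: dict(DEFAULT_T2_SLICE_SD))
    component_s0: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENT_S0))
    noise_sigma: float = 1.0
    noise_model: str = "rician"
    lumen_center_offset: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 3 or not np.all(np.diff(te) > 0) or np.any(te <= 0):
            raise ValueError("echo_times must be >=3 strictly increasing positive values")
        if not self.outer_radius > self.lumen_radius > 0:
            raise ValueError("need outer_radius > lumen_radius > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        for cls, (mu, _sd) in self.component_t2.items():
            if mu <= 0:
                raise ValueError(f"T2 mean for {cls!r} must be > 0")

    @property
    def voxel_area(self) -> float:
        return self.voxel_size ** 2


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative settings.

    The defaults emulate the study conditions of a carotid endarterectomy
    cohort: 15 symptomatic and 11 asymptomatic plaques with group mean lipid
    areas of 31.5% and 15.8% of wall cross-section, an average of ~2.3
    usable slices per plaque, and significant hemorrhage on roughly a
    quarter of slices.
    """

    n_symptomatic: int = 15
    n_asymptomatic: int = 11
    lipid_fraction_mean_sym: float = 31.5
    lipid_fraction_mean_asym: float = 15.8
    lipid_fraction_sd: float = 10.0
    slice_fraction_sd: float = 4.0
    slices_per_plaque: float = 2.3
    iph_slice_probability: float = 0.27
    calcium_plaque_probability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_symptomatic < 1 or self.n_asymptomatic < 1:
            raise ValueError("cohort counts must be >= 1")
        for m in (self.lipid_fraction_mean_sym, self.lipid_fraction_mean_asym):
            if not 0 <= m <= 100:
                raise ValueError("group mean lipid fractions must lie in [0, 100]")
        for p in (self.iph_slice_probability, self.calcium_plaque_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.slices_per_plaque < 1:
            raise ValueError("slices_per_plaque must be >= 1")


@dataclass(frozen=True)
class HistologyEmulation:
    """Measurement model for the emulated histology gold standard.

    area_jitter_sd : absolute noise (percentage points) added to the true
        lipid area; default 5, chosen so slice-level agreement with the
        T2-map measurement lands in the R ~ 0.85 regime.
    bias : systematic offset in percentage points (default 0).
    """

    area_jitter_sd: float = 5.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.area_jitter_sd < 0:
            raise ValueError("area_jitter_sd must be >= 0")


@dataclass
class TissueMap:
    """Ground-truth tissue classes and relaxation parameters for one slice."""

    labels: np.ndarray  # int codes per LABELS
    true_t2: np.ndarray  # ms
    true_s0: np.ndarray  # signal units

    def __post_init__(self) -> None:
        if not (self.labels.shape == self.true_t2.shape == self.true_s0.shape):
            raise ValueError("labels, true_t2 and true_s0 must share one shape")

    @property
    def wall_mask(self) -> np.ndarray:
        return np.isin(self.labels, [LABEL_CODES["wall_fibrous"], LABEL_CODES["lipid"],
                                     LABEL_CODES["iph"], LABEL_CODES["calcium"]])

    @property
    def core_mask(self) -> np.ndarray:
        """Lipid-rich necrotic core: lipid plus hemorrhage voxels."""
        return np.isin(self.labels, [LABEL_CODES["lipid"], LABEL_CODES["iph"]])

    @property
    def calcium_mask(self) -> np.ndarray:
        return self.labels == LABEL_CODES["calcium"]

    def fraction(self, *classes: str) -> float:
        """Area of the given classes as % of wall area."""
        wall = self.wall_mask
        sel = np.isin(self.labels, [LABEL_CODES[c] for c in classes])
        return 100.0 * float((sel & wall).sum()) / float(wall.sum())


def _grid(config: PhantomConfig):
    n = config.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy = yy - c - config.lumen_center_offset[0]
    dx = xx - c - config.lumen_center_offset[1]
    return np.hypot(yy - c, xx - c), np.hypot(dy, dx), np.arctan2(yy - c, xx - c)


def wall_roi_from_config(config: PhantomConfig) -> WallROI:
    r_outer, r_lumen, _ = _grid(config)
    return WallROI(
        lumen_mask=r_lumen < config.lumen_radius,
        outer_mask=r_outer < config.outer_radius,
        voxel_area=config.voxel_area,
    )


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_tissue_map(
    config: PhantomConfig,
    lipid_fraction: float,
    iph_fraction: float = 0.0,
    seed: Optional[int] = None,
    calcium_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> TissueMap:
    """Build a ground-truth tissue map with the requested wall-area fractions.

    ``lipid_fraction`` and ``iph_fraction`` are percentages of wall area;
    the necrotic core occupies ``lipid_fraction + iph_fraction`` percent of
    the wall, with the hemorrhage sub-region placed at the centre of the
    lipid wedge (structurally inside the core).  Achieved fractions match
    requests to within one voxel of wall area (integer rounding).
    """
    for name, f in (("lipid_fraction", lipid_fraction), ("iph_fraction", iph_fraction),
                    ("calcium_fraction", calcium_fraction)):
        if f < 0:
            raise ValueError(f"{name} must be >= 0")
    total = lipid_fraction + iph_fraction + calcium_fraction
    if lipid_fraction + iph_fraction > 100 or total > 100:
        raise ValueError(
            "requested fractions exceed the wall: achievable maximum is 100% of wall area"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    r_outer, r_lumen, theta = _grid(config)
    lumen = r_lumen < config.lumen_radius
    outer = r_outer < config.outer_radius
    wall = outer & ~lumen
    n_wall = int(wall.sum())

    n_core = int(round(n_wall * (lipid_fraction + iph_fraction) / 100.0))
    n_iph = int(round(n_wall * iph_fraction / 100.0))
    n_ca = int(round(n_wall * calcium_fraction / 100.0))
    if n_core + n_ca > n_wall:
        ach = 100.0 * (n_wall - n_ca) / n_wall
        raise ValueError(
            f"requested fractions unachievable at this resolution; "
            f"achievable maximum core fraction is {ach:.1f}%"
        )

    labels = np.zeros(config.image_size * config.image_size, dtype=np.int16).reshape(wall.shape)
    labels[lumen] = LABEL_CODES["lumen"]
    labels[wall] = LABEL_CODES["wall_fibrous"]

    widx = np.flatnonzero(wall.ravel())
    th = theta.ravel()[widx]
    theta0 = rng.uniform(-math.pi, math.pi)

    def angdist(t, t0):
        d = np.abs((t - t0 + math.pi) % (2 * math.pi) - math.pi)
        return d

    # Contiguous angular wedge for the core; small score jitter gives a
    # slightly ragged but still contiguous boundary.
    score = angdist(th, theta0) + rng.normal(0.0, 0.03, size=widx.size)
    order = np.argsort(score, kind="stable")
    core_idx = widx[order[:n_core]]
    flat = labels.ravel()
    flat[core_idx] = LABEL_CODES["lipid"]
    # Hemorrhage occupies the wedge centre: spatially inside the lipid region.
    flat[core_idx[:n_iph]] = LABEL_CODES["iph"]

    if n_ca:
        rem = widx[order[n_core:]]
        score_ca = angdist(th, theta0 + math.pi)[np.argsort(score, kind="stable")[n_core:]]
        order_ca = np.argsort(score_ca, kind="stable")
        flat[rem[order_ca[:n_ca]]] = LABEL_CODES["calcium"]

    labels = flat.reshape(wall.shape)

    true_t2 = np.ones_like(labels, dtype=float)  # benign positive default
    true_s0 = np.zeros_like(labels, dtype=float)
    for cls, code in LABEL_CODES.items():
        sel = labels == code
        n_sel = int(sel.sum())
        if not n_sel:
            continue
        true_s0[sel] = config.component_s0.get(cls, 0.0)
        if cls in config.component_t2:
            mu, sd = config.component_t2[cls]
            lo, hi = config.component_t2_bounds.get(cls, (max(mu - 4 * sd, 1.0), mu + 4 * sd))
            # Per-slice shift of the component mean (between-subject tissue
            # variation); truncation bounds stay fixed.
            mu_s = mu + rng.normal(0.0, config.component_t2_slice_sd.get(cls, 0.0))
            true_t2[sel] = _truncnorm_draw(rng, mu_s, sd, lo, hi, n_sel)
    return TissueMap(labels=labels, true_t2=true_t2, true_s0=true_s0)


def simulate_echo_series(
    tissue: TissueMap,
    config: PhantomConfig,
    rng: Optional[np.random.Generator] = None,
    slice_index: int = 0,
) -> EchoSeries:
    """Forward-simulate the multi-echo acquisition of a tissue map.

    The noiseless voxel value at echo time TE is ``S0 * exp(-TE/T2)``;
    voxels with S0 = 0 emit nothing.  Noise follows ``config.noise_model``:
    Rician noise is the magnitude of a complex Gaussian perturbation of the
    true signal (magnitude MRI); Gaussian noise is additive, clipped at zero
    to preserve magnitude non-negativity.
    """
    te = np.asarray(config.echo_times, dtype=float)
    if te.size == 0:
        raise ValueError("echo_times must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    with np.errstate(divide="ignore"):
        decay = np.exp(-te[:, None, None] / tissue.true_t2[None, :, :])
    signal = tissue.true_s0[None, :, :] * decay
    sig = config.noise_sigma
    if sig > 0:
        if config.noise_model == "rician":
            g1 = rng.normal(0.0, sig, size=signal.shape)
            g2 = rng.normal(0.0, sig, size=signal.shape)
            signal = np.hypot(signal + g1, g2)
        else:
            signal = np.clip(signal + rng.normal(0.0, sig, size=signal.shape), 0.0, None)
    return EchoSeries(
        data=signal,
        echo_times=te,
        slice_index=slice_index,
        voxel_area=config.voxel_area,
        slice_thickness=config.slice_thickness,
    )


@dataclass
class SliceData:
    """One generated slice: images, ROI and paired ground truth."""

    plaque_id: str
    slice_index: int
    tissue: TissueMap
    roi: WallROI
    series: Optional[EchoSeries]
    histology_lipid_pct: float
    true_core_pct: float
    true_iph_pct: float

    @property
    def iph_core_share(self) -> float:
        """Hemorrhage area as a fraction of the necrotic core area."""
        if self.true_core_pct <= 0:
            return 0.0
        return self.true_iph_pct / self.true_core_pct


@dataclass
class PlaqueData:
    plaque_id: str
    symptomatic: bool
    quality: int
    stenosis_pct: float
    calcium_fraction_pct: float
    slices: list

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def _draw_slice_fractions(rng, spec: CohortSpec, plaque_core: float):
    core = float(np.clip(plaque_core + rng.normal(0.0, spec.slice_fraction_sd), 0.0, 85.0))
    iph = 0.0
    if rng.uniform() < spec.iph_slice_probability and core > 0:
        share = rng.uniform(0.15, 0.9)
        iph = float(min(core, max(6.0, share * core)))
    return core, iph


def make_cohort(
    spec: CohortSpec,
    config: PhantomConfig,
    emulation: Optional[HistologyEmulation] = None,
    simulate_images: bool = True,
) -> tuple[list, pd.DataFrame]:
    """Generate the full synthetic cohort.

    Returns the list of :class:`PlaqueData` and a per-plaque metadata table
    (plaque_id, symptomatic, quality, stenosis_pct, n_slices, true mean core
    fraction).  Bit-reproducible for fixed ``(spec.seed, config.seed)``.
    Setting ``simulate_images=False`` skips image synthesis (tissue maps and
    histology only), which is convenient for statistical checks on the
    generative model itself.
    """
    emulation = emulation or HistologyEmulation()
    ss = np.random.SeedSequence([spec.seed, config.seed])
    rng = np.random.default_rng(ss)
    roi = wall_roi_from_config(config)

    plaques: list[PlaqueData] = []
    rows = []
    groups = [(True, spec.n_symptomatic, spec.lipid_fraction_mean_sym),
              (False, spec.n_asymptomatic, spec.lipid_fraction_mean_asym)]
    k = 0
    for symptomatic, n, mean in groups:
        for _ in range(n):
            pid = f"P{k:03d}"
            k += 1
            plaque_core = float(np.clip(rng.normal(mean, spec.lipid_fraction_sd), 1.0, 80.0))
            n_slices = 1 + int(rng.poisson(spec.slices_per_plaque - 1.0))
            quality = int(rng.choice([3, 4, 5], p=[0.3, 0.4, 0.3]))
            stenosis = float(np.clip(rng.normal(82.0, 8.0), 50.0, 99.0))
            if rng.uniform() < spec.calcium_plaque_probability:
                calcium = float(rng.uniform(10.0, 25.0))
            else:
                calcium = float(rng.uniform(0.0, 3.0))
            slices = []
            for si in range(n_slices):
                core, iph = _draw_slice_fractions(rng, spec, plaque_core)
                lipid = core - iph
                tissue = make_tissue_map(
                    config, lipid, iph, calcium_fraction=calcium, rng=rng
                )
                series = simulate_echo_series(tissue, config, rng=rng, slice_index=si) \
                    if simulate_images else None
                true_core = tissue.fraction("lipid", "iph")
                true_iph = tissue.fraction("iph")
                hist = float(np.clip(
                    true_core + emulation.bias + rng.normal(0.0, emulation.area_jitter_sd),
                    0.0, 100.0))
                slices.append(SliceData(
                    plaque_id=pid, slice_index=si, tissue=tissue, roi=roi,
                    series=series, histology_lipid_pct=hist,
                    true_core_pct=true_core, true_iph_pct=true_iph,
                ))
            plaques.append(PlaqueData(
                plaque_id=pid, symptomatic=symptomatic, quality=quality,
                stenosis_pct=stenosis, calcium_fraction_pct=calcium, slices=slices,
            ))
            rows.append({
                "plaque_id": pid,
                "symptomatic": symptomatic,
                "quality": quality,
                "stenosis_pct": stenosis,
                "calcium_fraction_pct": calcium,
                "n_slices": n_slices,
                "true_mean_core_pct": float(np.mean([s.true_core_pct for s in slices])),
                "histology_mean_pct": float(np.mean([s.histology_lipid_pct for s in slices])),
            })
    return plaques, pd.DataFrame(rows)


def make_rescan_pair(
    plaque: PlaqueData,
    config: PhantomConfig,
    seed: int,
    shift_max: int = 1,
) -> tuple[list, list]:
    """Re-acquire one plaque twice: same tissue, independent noise.

    Each scan re-simulates every slice with fresh noise and applies a small
    random integer in-plane shift to the ROI (patient repositioning error,
    up to ``shift_max`` voxels per axis).  With ``shift_max=0`` and
    ``config.noise_sigma=0`` both scans are identical to the original.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    scans = []
    for _scan in range(2):
        if shift_max > 0:
            dy, dx = rng.integers(-shift_max, shift_max + 1, size=2)
        else:
            dy = dx = 0
        out = []
        for s in plaque.slices:
            series = simulate_echo_series(s.tissue, config, rng=rng, slice_index=s.slice_index)
            roi = WallROI(
                lumen_mask=np.roll(s.roi.lumen_mask, (dy, dx), axis=(0, 1)),
                outer_mask=np.roll(s.roi.outer_mask, (dy, dx), axis=(0, 1)),
                voxel_area=s.roi.voxel_area,
            )
            out.append(replace(s, series=series, roi=roi))
        scans.append(out)
    return scans[0], scans[1]
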