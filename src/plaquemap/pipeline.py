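"""End-to-end orchestration of the synthetic T2-mapping study.

``run_synthetic_study`` mirrors the study flow: generate the cohort, apply
the image-quality filter, fit T2 maps, calibrate segmentation thresholds
against the emulated histology (grid search + leave-one-out
cross-validation), segment every slice at the calibrated pair, aggregate to
plaques, run the clinical statistics battery, and score plaque-type
agreement.  A separate scan-rescan sub-study quantifies test-retest
reproducibility.

One global seed fans out to fixed per-stage substreams through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives the main cohort,
child 1 the rescan cohort.  Identical config + seed therefore reproduces
every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .aha import AHARules, PlaqueFeatures, agreement_table, classify_plaque
from .calibration import CalibrationGrid, CalibrationSlice, ThresholdCalibrator, compare_modes
from .phantom import (CohortSpec, HistologyEmulation, PhantomConfig, make_cohort,
                      make_rescan_pair)
from .relaxometry import FitOptions, fit_slice
from .segmentation import (classify_voxels, filter_quality, measure_slice,
                           summarize_plaque)
from . import stats as cstats

__all__ = ["RunConfig", "StudyBundle", "run_synthetic_study", "fit_cohort"]

log = logging.getLogger("plaquemap")


@dataclass
class RunConfig:
    """One config object driving every stage."""

    seed: int = 0
    outdir: Optional[str] = None
    write_images: bool = False
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    emulation: HistologyEmulation = field(default_factory=HistologyEmulation)
    grid: CalibrationGrid = field(default_factory=CalibrationGrid)
    fit_options: FitOptions = field(default_factory=FitOptions)
    aha_rules: AHARules = field(default_factory=AHARules)
    n_rescan_plaques: int = 9
    rescan_lipid_mean: float = 20.3
    rescan_lipid_sd: float = 9.0
    min_quality: int = 3
    iph_significance_pct: float = 5.0
    large_lrnc_cutoff_pct: float = 25.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON config; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sub = {
            "phantom": PhantomConfig, "cohort": CohortSpec,
            "emulation": HistologyEmulation, "grid": CalibrationGrid,
            "fit_options": FitOptions, "aha_rules": AHARules,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in sub:
                if key == "phantom" and "echo_times" in val:
                    val["echo_times"] = tuple(val["echo_times"])
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def resolved_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        cohort_ss, rescan_ss = ss.spawn(2)
        return {
            "cohort": int(cohort_ss.generate_state(1)[0] % (2 ** 31)),
            "rescan": int(rescan_ss.generate_state(1)[0] % (2 ** 31)),
        }


@dataclass
class StudyBundle:
    """All results of one synthetic study run."""

    calibration: dict
    slices: pd.DataFrame
    plaques: pd.DataFrame
    stats: dict
    aha: pd.DataFrame
    seed: int


def fit_cohort(plaques, options: Optional[FitOptions] = None) -> dict:
    """Fit T2 maps for every slice of every plaque.

    Returns ``{(plaque_id, slice_index): T2Map}``.  Slices are fitted one
    batch each (the fitter is vectorized over voxels).
    """
    options = options or FitOptions()
    maps = {}
    for p in plaques:
        for s in p.slices:
            maps[(p.plaque_id, s.slice_index)] = fit_slice(s.series, s.roi, options)
    return maps


def _measure_cohort(plaques, maps, thresholds, config: RunConfig):
    slice_rows, measurements = [], {}
    for p in plaques:
        per_plaque = []
        for s in p.slices:
            t2map = maps[(p.plaque_id, s.slice_index)]
            cmap = classify_voxels(t2map, s.roi, thresholds, mode="dual")
            meas = measure_slice(
                cmap, s.roi, iph_significance_pct=config.iph_significance_pct,
                plaque_id=p.plaque_id, slice_index=s.slice_index,
                histology_lipid_pct=s.histology_lipid_pct,
                include_invalid_in_denominator=True,
            )
            per_plaque.append(meas)
            slice_rows.append({
                "plaque_id": p.plaque_id,
                "slice_index": s.slice_index,
                "lipid_area_pct": meas.lipid_area_pct,
                "iph_area_pct": meas.iph_area_pct,
                "wall_area_mm2": meas.wall_area_mm2,
                "significant_iph": meas.significant_iph,
                "histology_lipid_pct": s.histology_lipid_pct,
                "true_core_pct": s.true_core_pct,
                "iph_core_share": s.iph_core_share,
            })
        measurements[p.plaque_id] = per_plaque
    return pd.DataFrame(slice_rows), measurements


def _rescan_study(config: RunConfig, thresholds, seed: int) -> cstats.ReproducibilityReport:
    spec = CohortSpec(
        n_symptomatic=max(1, config.n_rescan_plaques // 2),
        n_asymptomatic=max(1, config.n_rescan_plaques - config.n_rescan_plaques // 2),
        lipid_fraction_mean_sym=config.rescan_lipid_mean,
        lipid_fraction_mean_asym=config.rescan_lipid_mean,
        lipid_fraction_sd=config.rescan_lipid_sd,
        slices_per_plaque=config.cohort.slices_per_plaque,
        iph_slice_probability=config.cohort.iph_slice_probability,
        seed=seed,
    )
    plaques, _ = make_cohort(spec, config.phantom, config.emulation)
    a_vals, b_vals, ids = [], [], []
    for i, p in enumerate(plaques):
        scan_a, scan_b = make_rescan_pair(p, config.phantom, seed=seed + 1000 + i)
        per_scan = []
        for scan in (scan_a, scan_b):
            vals = []
            for s in scan:
                t2map = fit_slice(s.series, s.roi, config.fit_options)
                cmap = classify_voxels(t2map, s.roi, thresholds, mode="dual")
                meas = measure_slice(cmap, s.roi, plaque_id=p.plaque_id,
                                     slice_index=s.slice_index,
                                     include_invalid_in_denominator=True)
                vals.append(meas.lipid_area_pct)
            per_scan.append(float(np.mean(vals)))
        a_vals.append(per_scan[0])
        b_vals.append(per_scan[1])
        ids.append(p.plaque_id)
    return cstats.reproducibility_report(a_vals, b_vals, ids)


def run_synthetic_study(config: RunConfig) -> StudyBundle:
    """Run the full synthetic study; see the module docstring for stages."""
    seeds = config.resolved_seeds()
    spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])

    log.info("generating cohort (%d + %d plaques)", spec.n_symptomatic, spec.n_asymptomatic)
    plaques, meta = make_cohort(spec, config.phantom, config.emulation)

    meta_kept, n_excluded = filter_quality(meta, min_quality=config.min_quality)
    kept_ids = set(meta_kept["plaque_id"])
    plaques = [p for p in plaques if p.plaque_id in kept_ids]
    log.info("quality filter: %d plaques retained, %d excluded", len(plaques), n_excluded)

    log.info("fitting T2 maps")
    maps = fit_cohort(plaques, config.fit_options)

    log.info("calibrating thresholds")
    cal_slices = [
        CalibrationSlice.from_t2map(
            maps[(p.plaque_id, s.slice_index)], s.roi, s.histology_lipid_pct,
            plaque_id=p.plaque_id, slice_index=s.slice_index,
            iph_core_share=s.iph_core_share,
        )
        for p in plaques for s in p.slices
    ]
    cal = ThresholdCalibrator(cal_slices, config.grid).fit(run_loocv=True)
    modes = compare_modes(cal_slices, config.grid)

    slices_df, measurements = _measure_cohort(plaques, maps, cal.best_pair, config)

    summaries, aha_rows = [], []
    for p in plaques:
        summ = summarize_plaque(measurements[p.plaque_id],
                                config.phantom.slice_thickness, symptomatic=p.symptomatic)
        summaries.append({
            "plaque_id": p.plaque_id,
            "symptomatic": p.symptomatic,
            "mean_lipid_area_pct": summ.mean_lipid_area_pct,
            "volume_mm3": summ.volume_mm3,
            "n_slices": summ.n_slices,
            "stenosis_pct": p.stenosis_pct,
            "quality": p.quality,
            "histology_mean_pct": float(np.mean(
                [s.histology_lipid_pct for s in p.slices])),
        })
        # Predicted type from T2-map measures + calcium mask; reference type
        # from the generative ground truth through the same rule set.
        pred = classify_plaque(PlaqueFeatures(
            lipid_area_pct=min(100.0, summ.mean_lipid_area_pct),
            significant_iph=any(m.significant_iph for m in measurements[p.plaque_id]),
            calcium_area_pct=float(np.mean([s.tissue.fraction("calcium") for s in p.slices])),
        ), config.aha_rules)
        ref = classify_plaque(PlaqueFeatures(
            lipid_area_pct=float(np.mean([s.true_core_pct for s in p.slices])),
            significant_iph=any(s.true_iph_pct > config.iph_significance_pct
                                for s in p.slices),
            calcium_area_pct=float(np.mean([s.tissue.fraction("calcium") for s in p.slices])),
        ), config.aha_rules)
        aha_rows.append({"plaque_id": p.plaque_id, "predicted": pred.value,
                         "reference": ref.value})
    plaques_df = pd.DataFrame(summaries)
    aha_df = pd.DataFrame(aha_rows)

    log.info("computing statistics")
    agree = cstats.agreement_report(
        slices_df["lipid_area_pct"], slices_df["histology_lipid_pct"],
        plaques_df["mean_lipid_area_pct"], plaques_df["histology_mean_pct"],
    )
    disc = cstats.discrimination_report(plaques_df,
                                        large_cutoff=config.large_lrnc_cutoff_pct)
    repro = _rescan_study(config, cal.best_pair, seeds["rescan"])
    conf = agreement_table([r["predicted"] for r in aha_rows],
                           [r["reference"] for r in aha_rows])
    kappa = cstats.cohens_kappa(conf.to_numpy())

    calibration = {
        "best_t2l_ms": cal.best_pair.t2l,
        "best_t2h_ms": cal.best_pair.t2h,
        "best_r": cal.best_r,
        "best_p": cal.best_p,
        "rmse_pct": cal.rmse_pct,
        "loocv_r": cal.loocv_r,
        "loocv_p": cal.loocv_p,
        "grid_step_ms": config.grid.step,
        "mode_comparison": {
            "dual_r": modes.dual_r,
            "single_low_r": modes.single_low_r,
            "single_low_t2l_ms": modes.single_low_t2l,
            "dual_r_heavy_iph_excluded": modes.dual_r_excl,
            "single_low_r_heavy_iph_excluded": modes.single_low_r_excl,
            "n_heavy_iph_excluded": modes.n_excluded,
            "subset_definition": modes.subset_definition,
        },
    }
    stats_out = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_plaques": len(plaques),
        "n_slices": int(len(slices_df)),
        "n_excluded_quality": n_excluded,
        "agreement": dataclasses.asdict(agree),
        "discrimination": {
            k: v for k, v in dataclasses.asdict(disc).items() if k != "roc"
        },
        "reproducibility": {
            "icc": repro.icc, "icc_ci_low": repro.icc_ci_low,
            "icc_ci_high": repro.icc_ci_high, "cov_pct": repro.cov_pct,
            "n_pairs": repro.n_pairs,
        },
        "aha": {"kappa": kappa.kappa, "agreement_pct": kappa.agreement_pct,
                "n": kappa.n},
    }

    bundle = StudyBundle(calibration=calibration, slices=slices_df,
                         plaques=plaques_df, stats=stats_out, aha=aha_df,
                         seed=config.seed)
    if config.outdir:
        _persist(bundle, plaques, maps, config)
    return bundle


def _persist(bundle: StudyBundle, plaques, maps, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_json(_jsonable(bundle.calibration), out / "calibration.json")
    pio.write_json(_jsonable(bundle.stats), out / "stats.json")
    bundle.slices.to_csv(out / "slices.csv", index=False)
    bundle.plaques.to_csv(out / "plaques.csv", index=False)
    bundle.aha.to_csv(out / "aha.csv", index=False)
    if config.write_images:
        img = out / "images"
        for p in plaques:
            for s in p.slices:
                stem = img / f"{p.plaque_id}_s{s.slice_index}"
                pio.write_echo_series(s.series, img / f"{p.plaque_id}_s{s.slice_index}_echoes.nii.gz",
                                      seed=config.seed)
                pio.write_roi(s.roi, img / f"{p.plaque_id}_s{s.slice_index}_lumen.nii.gz",
                              img / f"{p.plaque_id}_s{s.slice_index}_outer.nii.gz")
                pio.write_t2map(maps[(p.plaque_id, s.slice_index)], stem)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
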