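# plaquemap

Quantitative T2 relaxometry and lipid quantification for carotid
atherosclerotic plaque MRI — with a fully synthetic validation harness.

## The problem

The lipid-rich necrotic core (LRNC) is the hallmark of vulnerable carotid
plaque: symptomatic plaques carry roughly twice the lipid of asymptomatic
ones at similar stenosis. Multi-echo spin-echo (MESE) imaging lets the core
be measured non-invasively: each voxel's magnitude signal decays as

    S(TE) = S0 · exp(−TE / T2)

and fitting this monoexponential voxel by voxel yields a quantitative T2
map. Within the vessel wall, lipid core has short T2, fibrous wall
intermediate T2, and recent intraplaque hemorrhage (IPH) — which sits
structurally inside the core — the longest T2 of all components. A dual
threshold pair (T2L, T2H) therefore segments the core: wall voxels with
T2 < T2L or T2 > T2H are LRNC, and the lipid area is reported as a
percentage of the wall cross-section. The threshold pair is calibrated
against histology by exhaustive grid search (T2L in 30–50 ms, T2H in
70–120 ms) maximizing the Pearson correlation with histological lipid
area, with out-of-sample performance estimated by leave-one-out
cross-validation.

`plaquemap` implements this entire analysis as a tested Python package:

- **`plaquemap.relaxometry`** — vectorized nonlinear (Levenberg–Marquardt)
  monoexponential fitting; `T2Relaxometry(series, roi).fit()` returns a
  `T2MapResult` with T2/S0/R² maps and per-voxel validity flags.
- **`plaquemap.segmentation`** — dual-threshold voxel classification,
  per-slice lipid/IPH area bookkeeping, plaque summaries, quality filter.
- **`plaquemap.calibration`** — `ThresholdCalibrator(slices, grid).fit()`:
  grid search + LOOCV with deterministic tie-breaking.
- **`plaquemap.stats`** — Pearson/Bland–Altman agreement, Student t tests,
  ROC with Youden-optimal cutoff, chi-square on the ≥25% large-core rule,
  scan-rescan ICC(2,1) with F-based CI, within-subject CoV, Cohen's kappa.
- **`plaquemap.aha`** — rule-based modified AHA plaque typing (IV–V / VI /
  VII / VIII) and confusion-table agreement.
- **`plaquemap.phantom`** — a seeded synthetic study generator: annular
  vessel-wall phantoms with component-specific T2 distributions, Rician
  noise, histology ground truth with measurement jitter, two clinical
  cohorts, and scan-rescan replicate pairs — so every pipeline stage is
  verifiable without patient data.
- **`plaquemap.pipeline` / CLI** — end-to-end orchestration from one
  seeded config.

## Worked example

```python
import numpy as np
from plaquemap import EchoSeries, T2Relaxometry
from plaquemap.pipeline import RunConfig, run_synthetic_study

# one voxel: noiseless decay with T2 = 50 ms
te = np.linspace(9, 127, 14)
from plaquemap import fit_voxel
print(fit_voxel(100 * np.exp(-te / 50), te))
# VoxelFit(t2=50.0, s0=100.0, rsq=1.0, valid=True, reason='ok', offset=0.0)

# the full synthetic study: 26 plaques, ~60 slices, calibration + statistics
bundle = run_synthetic_study(RunConfig(seed=1))
c = bundle.calibration
print(c["best_t2l_ms"], c["best_t2h_ms"], round(c["best_r"], 3),
      round(c["loocv_r"], 3))
# 42.0 88.0 0.827 0.812
```

At seed 1 the calibrated thresholds are (42, 88) ms — the generator's
construction places them at (42, 90), and recovery is within 2 ms in ~90%
of seeds — with in-sample slice-level R = 0.83 against the emulated
histology and LOOCV R = 0.81. The same bundle carries group statistics
(mean lipid 34.7% symptomatic vs 18.6% asymptomatic, t-test p = 0.0003,
ROC AUC = 0.90), scan-rescan reproducibility (ICC = 0.98, CoV = 6.4%), and
plaque-type agreement (kappa = 0.72).

Or from the shell:

```bash
plaquemap run-all --seed 1 --out results/run1
plaquemap simulate --seed 1 --out scratch/sim      # NIfTI + CSV artifacts
plaquemap fit scratch/sim/P000_s0_echoes.nii.gz \
    --outer-mask scratch/sim/P000_s0_outer.nii.gz \
    --lumen-mask scratch/sim/P000_s0_lumen.nii.gz \
    --out-stem scratch/maps/P000_s0
```

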