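# Methods

This note documents the models, conventions and numerical choices behind
`plaquemap`, and what the synthetic validation harness does and does not
demonstrate.

## Relaxometry

Each voxel's echo train is modelled as a two-parameter monoexponential,
`S(TE) = S0·exp(−TE/T2)`, fitted by nonlinear least squares on the
untransformed magnitudes. An optional three-parameter variant adds a
constant offset `C` (off by default; fat-suppressed MESE data rarely needs
it). The fitter is a damped Gauss–Newton (Levenberg–Marquardt) iteration
vectorized across voxels:

- **Initialization** — log-linear least squares on the positive samples
  (`ln S` vs `TE`); exact for noiseless data, so the noiseless phantom
  round-trip recovers T2 at machine precision.
- **Convergence** — relative SSE change ≤ 1e−8 on an accepted step, cap of
  200 iterations, per-voxel damping.
- **Bounds** — T2 clamped to [1, 1000] ms. A fit pinned at a bound is
  reported but flagged invalid (`bound`), so segmentation decides its
  fate; all-zero or non-finite trains are flagged `no_signal`. An optional
  R² floor (`min_rsq`, off by default) can additionally flag low-quality
  fits; it is off because the study design did not state any pre-fit
  SNR exclusion.
- **R²** is 1 − SSE/TSS clipped to [0, 1].

## Segmentation conventions

Wall voxels with T2 strictly below T2L or strictly above T2H are core
(`lrnc_short` / `lrnc_iph`); boundary-equal voxels are not core. The 5%
IPH-significance rule is strict (`> 5%`) and its denominator is the wall
cross-section, consistent with every other percentage in the package.
Per-plaque lipid is the unweighted mean over slices (area-weighted
available); plaque volume is Σ wall-area × slice thickness.

**Denominators.** The public `measure_slice` excludes invalid-fit voxels
from numerator and denominator by default, with a switch to keep them in
the denominator. The pipeline sets that switch: calcium is modelled as a
signal void, so its voxels always fit invalid, and excluding them would
inflate lipid percentages by 1/(1 − calcium fraction) relative to
histology, whose denominator is the full cross-section. With the full-wall
denominator the measured and histological percentages share one scale.

## Threshold calibration

The grid search evaluates every (T2L, T2H) pair (defaults 30–50 / 70–120
ms, 1 ms step) by the Pearson correlation between measured and
histological lipid areas over slices. Per slice, the lipid percentage at
any pair depends only on how many wall T2 values fall strictly below T2L
and strictly above T2H, so one sorted pass per slice yields the whole
surface exactly (no refitting). Ties in R (exact plateaus arise when no
voxel lies between two candidate thresholds) are broken deterministically:
lower RMSE, then lower T2L, then lower T2H. LOOCV re-runs the search on
n−1 slices and applies each winning pair to the held-out slice; both the
in-sample maximum R and the cross-validated R are first-class outputs
because they answer different questions (fit vs. generalization).

## The synthetic study generator

The phantom is a circular annulus (lumen radius 6, outer radius 16 voxels
on a 64×64 grid; 0.2 mm voxels, 2 mm slices → wall ≈ 28 mm², plaque
volumes ≈ 130 mm³ at ~2.3 slices per plaque). Plaque components occupy
contiguous angular wedges: the necrotic core wedge with hemorrhage at its
centre (hemorrhage is structurally inside the core), calcium opposite.
Requested area fractions are met to within one voxel.

Per-voxel true T2 is drawn from truncated normals per component, with a
per-slice random shift of each component mean (between-subject tissue
variation):

| component | mean ± sd (ms) | truncation (ms) | slice-mean sd (ms) |
|---|---|---|---|
| lipid core | 36 ± 4 | (15, 41) | 3 |
| fibrous wall | 60 ± 10 | (42, 90) | 12 |
| recent IPH | 94 ± 1.5 | (92, 160) | 0.5 |
| lumen (suppressed) | 150 ± 30 | (80, 250) | 0 |

Calcium is a signal void (S0 ≈ 2 vs. 100 for wall tissue) rather than a
T2 class, with its mask emitted for plaque typing; lumen signal is
suppressed to S0 ≈ 8 (black-blood preparation). Noise is Rician by
default (magnitude of a complex Gaussian perturbation, σ = 1 signal unit,
i.e. SNR ≈ 100 at the first echo), Gaussian available for analytic tests.

Two design choices deserve emphasis because they were forced by
identifiability analysis, not aesthetics:

1. **Distributions abut the 42/90 ms thresholds.** With guard gaps around
   the thresholds the R surface is flat across the gap and the calibrated
   pair is decided by tie-breaking and noise, landing anywhere in the gap.
   Placing the truncation bounds essentially at the thresholds makes a
   1 ms move misclassify real tissue, so the optimum is pinned.
2. **Per-slice component-mean variation.** Without it, the fibrous
   fraction of every slice is exactly `100 − core − calcium`, an affine
   function of the core fraction — and Pearson correlation is invariant
   to affine transforms, so capturing arbitrary amounts of fibrous wall
   would be free and the lower threshold would drift upward to wherever
   noise-spilled lipid estimates end. Between-slice variation of the
   fibrous T2 distribution makes over-inclusion genuinely noisy and
   restores the cost structure that real between-patient variation
   provides.

The narrow IPH distribution (94 ± 1.5 ms) is likewise an identifiability
choice: hemorrhage appears on only ~27% of slices, so a diffuse IPH
distribution leaves the upper threshold weakly identified at n ≈ 60
slices. With these constants the calibrated pair lands within 2 ms of
(42, 90) in ~90% of seeded cohorts.

Cohort structure: 15 symptomatic and 11 asymptomatic plaques with true
mean lipid areas 31.5% and 15.8% (between-plaque sd 10, between-slice sd
4, clipped to [1, 80]); slices per plaque 1 + Poisson(1.3) (mean 2.3,
~60 slices per cohort); significant hemorrhage on ~27% of slices with the
hemorrhage share of the core uniform on (0.15, 0.9) and floored at 6% of
wall (so that roughly half of hemorrhagic slices are heavily infiltrated);
calcified plaques (calcium 10–25% of wall) with probability 0.25;
stenosis ~ N(82, 8)% in both groups (a nuisance covariate); quality
scores drawn from {3, 4, 5} — the configured cohort counts represent the
analyzable, post-quality-filter cohort, so the pipeline's filter passes
everything at defaults and is exercised separately in tests. Histology emulation adds
N(0, 5%) absolute jitter (and an optional systematic bias, default 0) to
the true core fraction, which puts slice-level agreement in the R ≈ 0.85
regime. Scan-rescan pairs re-simulate the same tissue with fresh noise and
an integer ROI shift of up to ±1 voxel per scan (repositioning error).

All generation is driven by `numpy.random.SeedSequence`; a cohort is
bit-reproducible from `(spec.seed, config.seed)`, and the pipeline fans a
single global seed into fixed per-stage substreams (child 0: main cohort,
child 1: rescan study).

**What passing tests do not show.** The phantom has no k-space blurring,
no through-plane partial volume, no motion, no B1/stimulated-echo effects,
and its component distributions are cleanly separable by construction;
real tissue T2 distributions overlap. Synthetic recovery therefore
validates the pipeline's correctness and its statistical machinery, not
the clinical accuracy of any particular threshold pair.

## Statistics

- **Pearson R** with two-sided p from the t transform (scipy).
- **Bland–Altman**: bias = mean(measured − reference), limits = bias ±
  1.96·sd (ddof 1).
- **Student t test**: pooled variance by default (Welch optional);
  summaries reported as mean ± SEM.
- **ROC**: AUC by the Mann–Whitney rank formulation (ties half); calling
  convention score ≥ cutoff → symptomatic; optimal cutoff maximizes
  Youden's J, ties resolved toward the lowest (most sensitive) cutoff;
  p-value from the two-sided Mann–Whitney test.
- **Chi-square** on the large-core rule (lipid ≥ 25%, inclusive) without
  continuity correction by default; the Yates-corrected variant is always
  reported alongside.
- **ICC**: two-way random effects, absolute agreement, single measurement
  — ICC(2,1) from the ANOVA mean squares; 95% CI by the standard
  F-distribution bounds with Satterthwaite df. Exact agreement returns
  ICC = 1 with a degenerate CI.
- **Within-subject CoV**: √(mean(d²)/2) over paired differences, divided
  by the grand mean — not an average of per-subject CVs.
- **Cohen's kappa**: (p_o − p_e)/(1 − p_e) on the K×K confusion table;
  the single-agreed-category degenerate case is defined as κ = 1.

Implementations lean on scipy where the definition is unambiguous
(pearsonr, ttest_ind, chi2_contingency); the conventions above that admit
variants (AUC tie handling, ICC formulation, CoV definition) are
implemented from their definitions and cross-checked in the test suite
against independent oracles (brute-force pair counting, hand ANOVA,
scikit-learn, pingouin).

## Plaque typing

Modified AHA typing for advanced lesions is a fixed precedence cascade
over quantitative features: significant hemorrhage → VI; calcium area >
10% → VII; lipid core ≥ 10% → IV–V; otherwise VIII (fibrous). Both
thresholds are configurable; calcium always comes from the input mask
(emulating identification on bright-blood angiography), never from T2.
The 5% hemorrhage-significance rule is reused for the VI criterion. This
cascade is this package's concrete reading of the scheme — the precedence
order and both cutoffs are declared configuration, not measured facts.

## Problem sizes

Default study size (64×64 phantom, 26 plaques, ~60 slices, 9 rescan
pairs) runs end-to-end in a few seconds; the repeated-cohort properties
in the test suite (threshold recovery and discrimination power over 100
seeded cohorts, 500 ICC coverage simulations, 10⁴ t-test null replicates)
were sized to keep the whole suite in a few minutes while leaving the
Monte-Carlo bounds comfortably away from their thresholds.

## Known limitations

- The generator emulates pre-matched slice pairs; histology–image
  location matching and its failure modes are out of scope.
- Lumen/outer-wall contours are inputs (or phantom-derived); no vessel
  segmentation is provided.
- No multi-exponential or T2-spectrum fitting; a voxel is one T2.
- The residual positive Bland–Altman bias (~2–5%) on synthetic cohorts
  comes from threshold-undershoot capturing the fibrous upper tail and
  from Rician floor bias at late echoes; it shrinks toward zero as the
  calibrated pair approaches the generating pair.
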