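"""Agreement and group-discrimination statistics for plaque lipid measures.

Implements the clinical statistics battery: Pearson correlation,
Bland-Altman agreement, Student t tests, relative group differences,
chi-square on the large-core (>=25% of wall area) rule, ROC discrimination
with Youden-optimal cutoff, scan-rescan intraclass correlation
(two-way random effects, absolute agreement, single measurement) with its
F-based confidence interval, within-subject coefficient of variation, and
Cohen's kappa for plaque-type agreement.

Standard distributions and omnibus tests come from scipy; the formulations
the field attaches a specific convention to (rank-based AUC with ties
counted half, ICC(2,1) from ANOVA mean squares, within-subject CoV via
root-mean-square paired differences) are implemented from their
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PearsonResult",
    "BlandAltmanResult",
    "TTestResult",
    "ROCResult",
    "Chi2Result",
    "ICCResult",
    "KappaResult",
    "AgreementReport",
    "DiscriminationReport",
    "ReproducibilityReport",
    "pearson_r",
    "bland_altman",
    "relative_difference",
    "two_sample_t",
    "roc_analysis",
    "chi2_large_lrnc",
    "chi2_from_table",
    "icc_absolute",
    "cov_within",
    "cohens_kappa",
    "agreement_report",
    "discrimination_report",
    "reproducibility_report",
]


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        side = "x" if np.std(x) == 0 else "y"
        raise ValueError(f"zero variance in {side}")
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


class BlandAltmanResult(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(measured, reference) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and 95% limits (bias +/- 1.96 SD)."""
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("need paired 1-D inputs with n >= 2")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, sd_diff=sd, n=m.size)


def relative_difference(group_a_mean: float, group_b_mean: float) -> float:
    """Relative difference (a - b) / b * 100, in percent."""
    if group_b_mean == 0:
        raise ValueError("reference mean is zero")
    return (group_a_mean - group_b_mean) / group_b_mean * 100.0


class TTestResult(NamedTuple):
    t: float
    p: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int


def two_sample_t(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided Student t test (pooled variance by default; Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue),
        mean_a=float(a.mean()), sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        mean_b=float(b.mean()), sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=a.size, n_b=b.size,
    )


@dataclass
class ROCResult:
    auc: float
    p: float
    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_positive: int
    n_negative: int


def roc_analysis(scores, labels) -> ROCResult:
    """ROC discrimination of a binary outcome by a continuous score.

    AUC uses the Mann-Whitney rank formulation (ties counted half); the
    p-value is the two-sided Mann-Whitney test of group separation.  The
    calling convention is score >= cutoff -> positive; the optimal cutoff
    maximizes Youden's J (ties resolved toward the lowest cutoff, i.e. the
    more sensitive rule).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n1 = int(lab.sum())
    n0 = int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    auc = (ranks[lab].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    p = float(sps.mannwhitneyu(s[lab], s[~lab], alternative="two-sided").pvalue)

    cuts = np.unique(s)[::-1]  # descending; score >= cut -> positive call
    tpr = np.array([(s[lab] >= c).mean() for c in cuts])
    fpr = np.array([(s[~lab] >= c).mean() for c in cuts])
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    cutoffs = np.concatenate([[np.inf], cuts])
    j = tpr - fpr
    jmax = j.max()
    # Among maximal-J points pick the lowest cutoff (most sensitive rule).
    best = np.flatnonzero(j >= jmax - 1e-12)[-1]
    return ROCResult(
        auc=float(auc), p=p, fpr=fpr, tpr=tpr, cutoffs=cutoffs,
        optimal_cutoff=float(cutoffs[best]),
        sensitivity=float(tpr[best]), specificity=float(1.0 - fpr[best]),
        youden_j=float(j[best]), n_positive=n1, n_negative=n0,
    )


class Chi2Result(NamedTuple):
    chi2: float
    p: float
    table: np.ndarray
    chi2_yates: float
    p_yates: float


def chi2_from_table(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, with and without Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        # a zero margin leaves the statistic undefined (zero expected cell)
        return Chi2Result(chi2=float("nan"), p=float("nan"), table=t.astype(int),
                          chi2_yates=float("nan"), p_yates=float("nan"))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    chi2y, py, _, _ = sps.chi2_contingency(t, correction=True)
    return Chi2Result(chi2=float(chi2), p=float(p), table=t.astype(int),
                      chi2_yates=float(chi2y), p_yates=float(py))


def chi2_large_lrnc(summaries: pd.DataFrame, cutoff: float = 25.0,
                    lipid_column: str = "mean_lipid_area_pct",
                    group_column: str = "symptomatic") -> Chi2Result:
    """Chi-square of symptom status against the large-core rule.

    A plaque has a large core when its lipid area is >= ``cutoff`` percent
    (inclusive boundary).  Rows of the 2x2 table are symptomatic yes/no,
    columns large-core yes/no.
    """
    sym = summaries[group_column].astype(bool).to_numpy()
    if sym.all() or not sym.any():
        raise ValueError("both classes must be present")
    large = summaries[lipid_column].to_numpy() >= cutoff
    table = np.array([
        [int((sym & large).sum()), int((sym & ~large).sum())],
        [int((~sym & large).sum()), int((~sym & ~large).sum())],
    ])
    return chi2_from_table(table)


class ICCResult(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n: int
    degenerate: bool


def icc_absolute(a, b, alpha: float = 0.05) -> ICCResult:
    """Scan-rescan ICC: two-way random effects, absolute agreement, single
    measurement (ICC(2,1)), from the ANOVA mean squares, with the standard
    F-distribution confidence bounds."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need paired 1-D inputs with n >= 3")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    degenerate = msr <= 1e-12

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 0.0

    if mse <= 1e-300 and msc <= 1e-300:  # exact agreement
        return ICCResult(1.0, 1.0, 1.0, msr, msc, mse, n, degenerate)

    # McGraw & Wong CI for ICC(A,1), Satterthwaite df.
    a_c = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b_c = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a_c):
        v = (a_c * msc + b_c * mse) ** 2 / (
            (a_c * msc) ** 2 / (k - 1) + (b_c * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:  # pragma: no cover - icc numerically 1 handled above
        lower = upper = 1.0
    return ICCResult(float(icc), float(lower), float(upper),
                     float(msr), float(msc), float(mse), n, degenerate)


def cov_within(a, b) -> float:
    """Within-subject coefficient of variation, percent.

    The within-subject SD is sqrt(mean(d^2)/2) over paired differences d
    (root-mean-square formulation), normalized by the grand mean.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired 1-D inputs with n >= 2")
    grand = np.concatenate([a, b]).mean()
    if grand == 0:
        raise ValueError("grand mean is zero")
    d = a - b
    sw = np.sqrt((d * d).mean() / 2.0)
    return float(sw / grand * 100.0)


class KappaResult(NamedTuple):
    kappa: float
    agreement_pct: float
    n: int


def cohens_kappa(confusion) -> KappaResult:
    """Cohen's kappa and observed agreement from a KxK confusion table."""
    t = np.asarray(confusion, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("confusion table must hold non-negative integer counts")
    total = t.sum()
    if total < 1:
        raise ValueError("empty confusion table")
    po = np.trace(t) / total
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / total ** 2
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return KappaResult(kappa=1.0, agreement_pct=100.0, n=int(total))
        raise ValueError("degenerate table: chance agreement is 1 but observed is not")
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=float(kappa), agreement_pct=float(po * 100.0), n=int(total))


# ---------------------------------------------------------------------------
# Report builders


@dataclass
class AgreementReport:
    pearson_r_slice: float
    pearson_p_slice: float
    pearson_r_plaque: float
    pearson_p_plaque: float
    bias: float
    loa_low: float
    loa_high: float
    rmse_pct: float
    n_slices: int
    n_plaques: int


def agreement_report(measured_slice, histology_slice,
                     measured_plaque, histology_plaque) -> AgreementReport:
    """Method-agreement summary at slice and plaque level."""
    rs = pearson_r(measured_slice, histology_slice)
    rp = pearson_r(measured_plaque, histology_plaque)
    ba = bland_altman(measured_slice, histology_slice)
    d = np.asarray(measured_slice, float) - np.asarray(histology_slice, float)
    return AgreementReport(
        pearson_r_slice=rs.r, pearson_p_slice=rs.p,
        pearson_r_plaque=rp.r, pearson_p_plaque=rp.p,
        bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
        rmse_pct=float(np.sqrt((d * d).mean())),
        n_slices=rs.n, n_plaques=rp.n,
    )


@dataclass
class DiscriminationReport:
    mean_sym: float
    sem_sym: float
    mean_asym: float
    sem_asym: float
    t_p_value: float
    relative_difference_pct: float
    auc: float
    auc_p: float
    optimal_cutoff_pct: float
    sensitivity: float
    specificity: float
    chi2: float
    chi2_p: float
    large_lrnc_cutoff_pct: float
    n_sym: int
    n_asym: int
    roc: Optional[ROCResult] = None


def discrimination_report(summaries: pd.DataFrame, large_cutoff: float = 25.0,
                          lipid_column: str = "mean_lipid_area_pct",
                          group_column: str = "symptomatic") -> DiscriminationReport:
    """Group comparison of per-plaque lipid area between clinical cohorts."""
    sym = summaries[group_column].astype(bool).to_numpy()
    vals = summaries[lipid_column].to_numpy(dtype=float)
    tt = two_sample_t(vals[sym], vals[~sym])
    roc = roc_analysis(vals, sym)
    chi = chi2_large_lrnc(summaries, cutoff=large_cutoff,
                          lipid_column=lipid_column, group_column=group_column)
    return DiscriminationReport(
        mean_sym=tt.mean_a, sem_sym=tt.sem_a,
        mean_asym=tt.mean_b, sem_asym=tt.sem_b,
        t_p_value=tt.p,
        relative_difference_pct=relative_difference(tt.mean_a, tt.mean_b),
        auc=roc.auc, auc_p=roc.p,
        optimal_cutoff_pct=roc.optimal_cutoff,
        sensitivity=roc.sensitivity, specificity=roc.specificity,
        chi2=chi.chi2, chi2_p=chi.p, large_lrnc_cutoff_pct=large_cutoff,
        n_sym=tt.n_a, n_asym=tt.n_b, roc=roc,
    )


@dataclass
class ReproducibilityReport:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    cov_pct: float
    n_pairs: int
    pairs: pd.DataFrame


def reproducibility_report(scan_a, scan_b, plaque_ids=None) -> ReproducibilityReport:
    """Scan-rescan reproducibility of per-plaque lipid area."""
    a = np.asarray(scan_a, dtype=float)
    b = np.asarray(scan_b, dtype=float)
    icc = icc_absolute(a, b)
    cov = cov_within(a, b)
    ids = list(plaque_ids) if plaque_ids is not None else list(range(a.size))
    table = pd.DataFrame({"plaque_id": ids, "scan_a_pct": a, "scan_b_pct": b,
                          "difference_pct": a - b})
    return ReproducibilityReport(
        icc=icc.icc, icc_ci_low=icc.ci_low, icc_ci_high=icc.ci_high,
        cov_pct=cov, n_pairs=a.size, pairs=table,
    )
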