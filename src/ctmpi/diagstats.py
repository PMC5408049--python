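"""Diagnostic statistics for per-territory CT-MPI measurements.

Covers the battery used to validate perfusion indices against invasive FFR:
contingency metrics with cluster-adjusted confidence intervals (territories
cluster within patients), ROC/AUC with DeLong variance and the DeLong test
for correlated AUCs, Youden-index threshold selection, Pearson correlation,
inter-reader agreement (ICC and Cohen's kappa), the combined MBF x TPR
score, group summaries with t-tests, and the DLP-to-effective-dose utility.

Orientation convention: for both MBF and TPR a *lower* value indicates
disease, so positives are score <= threshold and ROC statistics are
computed on negated scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "MetricWithCI",
    "RocResult",
    "YoudenResult",
    "GroupComparison",
    "contingency_metrics",
    "cluster_adjusted_ci",
    "diagnostic_performance",
    "roc_auc",
    "delong_compare",
    "delong_variance",
    "youden_threshold",
    "combined_score",
    "pearson_r",
    "icc_two_readers",
    "cohen_kappa",
    "effective_dose",
    "group_summary",
    "quadrant_counts",
    "round_half_away",
    "filter_mbf_range",
]

Z95 = 1.959963984540054


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for percentages)."""
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricWithCI:
    """A proportion (in %) with a 95 % Wald confidence interval, optionally
    cluster-adjusted; bounds clipped to [0, 100]."""

    estimate: float
    ci_low: float
    ci_high: float
    cluster_adjusted: bool = False


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    orientation: str = "lower"


@dataclass
class YoudenResult:
    threshold: float
    j: float
    sensitivity: float
    specificity: float


@dataclass
class GroupComparison:
    means: dict
    sds: dict
    ns: dict
    t: float
    p_value: float
    welch: bool


def contingency_metrics(t: ContingencyTable) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent (full
    precision; NaN where the denominator is zero)."""

    def frac(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "sensitivity": frac(t.tp, t.tp + t.fn),
        "specificity": frac(t.tn, t.tn + t.fp),
        "ppv": frac(t.tp, t.tp + t.fp),
        "npv": frac(t.tn, t.tn + t.fn),
        "accuracy": frac(t.tp + t.tn, t.total),
    }


def cluster_adjusted_ci(
    outcomes: np.ndarray,
    clusters: np.ndarray,
) -> MetricWithCI:
    """95 % Wald CI for a proportion of per-territory binary outcomes whose
    variance is taken across patient clusters (ratio-estimator form).

    var(p) = sum_i (x_i - p * n_i)^2 / N^2 over clusters i with n_i
    territories and x_i successes.  With one territory per cluster this is
    exactly the unadjusted binomial Wald variance p(1-p)/N; positively
    correlated outcomes within clusters inflate it (design effect > 1).
    """
    outcomes = np.asarray(outcomes, dtype=float)
    clusters = np.asarray(clusters)
    if outcomes.shape != clusters.shape:
        raise ValueError("outcomes and clusters must align")
    if len(np.unique(clusters)) < 2:
        raise ValueError("cluster adjustment needs at least 2 clusters")
    n_total = len(outcomes)
    p = outcomes.mean()
    resid_sq = 0.0
    adjusted = False
    for c in np.unique(clusters):
        sel = clusters == c
        n_i = int(sel.sum())
        adjusted |= n_i > 1
        resid_sq += (outcomes[sel].sum() - p * n_i) ** 2
    se = np.sqrt(resid_sq) / n_total
    est = 100.0 * p
    half = 100.0 * Z95 * se
    return MetricWithCI(
        estimate=est,
        ci_low=max(est - half, 0.0),
        ci_high=min(est + half, 100.0),
        cluster_adjusted=adjusted,
    )


def diagnostic_performance(
    df: pd.DataFrame,
    positive_col: str,
    reference_col: str = "ischaemic",
    cluster_col: str = "patient_id",
) -> dict:
    """Diagnostic-performance row: contingency table plus the five metrics, each with
    a cluster-adjusted CI over its own denominator subset."""
    pos = df[positive_col].to_numpy(bool)
    ref = df[reference_col].to_numpy(bool)
    clus = df[cluster_col].to_numpy()
    table = ContingencyTable(
        tp=int((pos & ref).sum()), fp=int((pos & ~ref).sum()),
        tn=int((~pos & ~ref).sum()), fn=int((~pos & ref).sum()),
    )
    subsets = {
        "sensitivity": (ref, pos),
        "specificity": (~ref, ~pos),
        "ppv": (pos, ref),
        "npv": (~pos, ~ref),
        "accuracy": (np.ones(len(df), bool), pos == ref),
    }
    metrics = {}
    for name, (sel, outcome) in subsets.items():
        if sel.sum() == 0 or len(np.unique(clus[sel])) < 2:
            metrics[name] = None
            continue
        metrics[name] = cluster_adjusted_ci(outcome[sel], clus[sel])
    return {"table": table, "metrics": metrics}


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "lower":
        return -np.asarray(scores, float)
    if orientation == "higher":
        return np.asarray(scores, float)
    raise ValueError("orientation must be 'lower' or 'higher'")


def _split(scores: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Placement values of the Mann-Whitney kernel (ties count 1/2) and the
    AUC they average to."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)   # per diseased subject
    v01 = cmp.mean(axis=0)   # per normal subject
    return v10, v01, float(cmp.mean())


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    orientation: str = "lower",
) -> RocResult:
    """ROC analysis with AUC by the Mann-Whitney construction (tie-corrected)
    and a DeLong-variance Wald CI.

    ``labels`` are True for diseased; with the default orientation a lower
    score indicates disease (the MBF/TPR convention).
    """
    s = _oriented(scores, orientation)
    pos, neg = _split(s, labels)
    _, _, auc = _placements(pos, neg)
    var = delong_variance(scores, labels, orientation)
    half = Z95 * np.sqrt(var)
    thresholds = np.unique(np.asarray(scores, float))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    raw = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    for i, c in enumerate(thresholds):
        call = raw <= c if orientation == "lower" else raw >= c
        sens[i] = (call & lab).sum() / lab.sum()
        spec[i] = (~call & ~lab).sum() / (~lab).sum()
    return RocResult(
        auc=auc,
        ci_low=max(auc - half, 0.0),
        ci_high=min(auc + half, 1.0),
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        orientation=orientation,
    )


def delong_variance(
    scores: np.ndarray,
    labels: np.ndarray,
    orientation: str = "lower",
) -> float:
    """DeLong variance of a single AUC from placement-value dispersion."""
    s = _oriented(scores, orientation)
    pos, neg = _split(s, labels)
    v10, v01, _ = _placements(pos, neg)
    m, n = len(pos), len(neg)
    var10 = v10.var(ddof=1) if m > 1 else 0.0
    var01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(var10 / m + var01 / n)


def delong_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    orientation: str = "lower",
) -> dict:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns AUCs, their difference, the variance of the difference from the
    placement-value covariance structure, the z statistic and the two-sided
    normal p value.
    """
    sa = _oriented(scores_a, orientation)
    sb = _oriented(scores_b, orientation)
    labels = np.asarray(labels, bool)
    if sa.shape != sb.shape or sa.shape != labels.shape:
        raise ValueError("paired scores and labels must align")
    pos_a, neg_a = _split(sa, labels)
    pos_b, neg_b = _split(sb, labels)
    v10a, v01a, auc_a = _placements(pos_a, neg_a)
    v10b, v01b, auc_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)

    def cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if len(u) > 1 else 0.0

    var_diff = (
        (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m
        + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    )
    diff = auc_a - auc_b
    if diff == 0.0:
        z, p = 0.0, 1.0
    elif var_diff <= 0:
        z, p = float("inf") * np.sign(diff), 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "diff": diff,
        "var_diff": float(var_diff),
        "z": float(z),
        "p_value": float(p),
    }


def youden_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    orientation: str = "lower",
) -> YoudenResult:
    """Optimal cut-point maximising J = sensitivity + specificity - 1.

    Candidates are the observed score values (inclusive comparison).  Ties
    are broken toward higher sensitivity, then toward the lower threshold.
    When the classes are perfectly separated (J = 1) the midpoint of the
    separating interval is returned instead of the boundary observation.
    """
    raw = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    _split(_oriented(raw, orientation), lab)   # validates classes present
    candidates = np.unique(raw)
    best: tuple[float, float, float, float] | None = None
    for c in candidates:
        call = raw <= c if orientation == "lower" else raw >= c
        sens = (call & lab).sum() / lab.sum()
        spec = (~call & ~lab).sum() / (~lab).sum()
        j = sens + spec - 1.0
        if best is None:
            best = (j, sens, spec, c)
            continue
        jb, sb, _, cb = best
        better = (j > jb + 1e-12
                  or (abs(j - jb) <= 1e-12 and sens > sb + 1e-12)
                  or (abs(j - jb) <= 1e-12 and abs(sens - sb) <= 1e-12
                      and ((orientation == "lower" and c < cb)
                           or (orientation == "higher" and c > cb))))
        if better:
            best = (j, sens, spec, c)
    j, sens, spec, thr = best
    if j >= 1.0 - 1e-12:
        if orientation == "lower":
            above = candidates[candidates > thr]
            if len(above):
                thr = (thr + above.min()) / 2.0
        else:
            below = candidates[candidates < thr]
            if len(below):
                thr = (thr + below.max()) / 2.0
    return YoudenResult(float(thr), float(j), float(sens), float(spec))


def combined_score(mbf: float, tpr: float) -> float:
    """Combined index MBF x TPR."""
    if not (np.isfinite(mbf) and np.isfinite(tpr)):
        raise ValueError("mbf and tpr must be finite")
    return float(mbf) * float(tpr)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def icc_two_readers(reader1: np.ndarray, reader2: np.ndarray) -> float:
    """Two-way mixed, absolute-agreement, single-measure intraclass
    correlation — ICC(A,1) — for two readers.

    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) with k = 2 readers
    and n subjects, from the two-way ANOVA mean squares.
    """
    y1 = np.asarray(reader1, float)
    y2 = np.asarray(reader2, float)
    if y1.shape != y2.shape or y1.ndim != 1 or len(y1) < 3:
        raise ValueError("need paired measurements with n >= 3")
    data = np.column_stack([y1, y2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


def icc_consistency(reader1: np.ndarray, reader2: np.ndarray) -> float:
    """Two-way mixed, consistency, single-measure ICC — ICC(C,1); ignores
    systematic reader offsets (used for the convention comparison)."""
    y1 = np.asarray(reader1, float)
    y2 = np.asarray(reader2, float)
    data = np.column_stack([y1, y2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msr = ss_rows / (n - 1)
    return float((msr - mse) / (msr + (k - 1) * mse))


def cohen_kappa(labels1: np.ndarray, labels2: np.ndarray) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) for paired categorical labels."""
    a = np.asarray(labels1)
    b = np.asarray(labels2)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("need paired label vectors")
    cats = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pe = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if pe >= 1.0:
        raise ValueError("expected agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def effective_dose(dlp_mgy_cm: float, k: float = 0.014) -> float:
    """Effective dose in mSv from the dose-length product: DLP x k, with the
    chest conversion factor k = 0.014 mSv/(mGy cm)."""
    if dlp_mgy_cm < 0:
        raise ValueError("dlp must be non-negative")
    return dlp_mgy_cm * k


def group_summary(
    values: np.ndarray,
    groups: np.ndarray,
    welch: bool = False,
) -> GroupComparison:
    """Per-group mean +/- sd and an unpaired two-sided t-test between the
    two groups (pooled-variance by default, Welch optional)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    keys = list(pd.unique(groups))
    if len(keys) != 2:
        raise ValueError("exactly two groups required")
    g0 = values[groups == keys[0]]
    g1 = values[groups == keys[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both groups need n >= 2")
    t, p = stats.ttest_ind(g0, g1, equal_var=not welch)
    return GroupComparison(
        means={keys[0]: float(g0.mean()), keys[1]: float(g1.mean())},
        sds={keys[0]: float(g0.std(ddof=1)), keys[1]: float(g1.std(ddof=1))},
        ns={keys[0]: len(g0), keys[1]: len(g1)},
        t=float(t),
        p_value=float(p),
        welch=welch,
    )


def quadrant_counts(
    mbf: np.ndarray,
    tpr: np.ndarray,
    ischaemic: np.ndarray | None = None,
    mbf_threshold: float = 76.0,
    tpr_threshold: float = 0.82,
) -> pd.DataFrame:
    """Counts of territories in the four MBF x TPR threshold quadrants
    (optionally split by reference status).  No combined decision rule is
    asserted; quadrant membership is reported as-is."""
    mbf = np.asarray(mbf, float)
    tpr = np.asarray(tpr, float)
    mbf_pos = mbf <= mbf_threshold
    tpr_pos = tpr <= tpr_threshold
    rows = []
    for mp in (True, False):
        for tp_ in (True, False):
            sel = (mbf_pos == mp) & (tpr_pos == tp_)
            row = {"mbf_positive": mp, "tpr_positive": tp_,
                   "n": int(sel.sum())}
            if ischaemic is not None:
                isc = np.asarray(ischaemic, bool)
                row["n_ischaemic"] = int((sel & isc).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def filter_mbf_range(
    df: pd.DataFrame,
    low: float = 50.0,
    high: float = 100.0,
    mbf_col: str = "mbf",
) -> pd.DataFrame:
    """Intermediate-MBF sub-analysis filter, inclusive on both bounds."""
    return df[(df[mbf_col] >= low) & (df[mbf_col] <= high)].copy()
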