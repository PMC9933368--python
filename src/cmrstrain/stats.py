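"""Cohort statistics: normality-gated group tests, ROC AUC, correlations.

The workflow applied to per-subject metric tables: each metric is tested
for normality per group (Anderson-Darling, alpha = 0.05); normally
distributed pairs are compared with Welch's unpaired t-test, anything
else with Mann-Whitney U.  Discrimination is summarized as the ROC AUC
(exactly the Mann-Whitney U statistic scaled to [0, 1], ties counted
half) with a Wilson-score confidence interval; correlations use
Spearman's rho with Bonferroni family correction, and multi-group
comparisons use one-way ANOVA with Tukey-HSD-adjusted pairwise p-values.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class StatsError(ValueError):
    """Raised for untestable samples (too small, constant, single class)."""


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


# ----------------------------------------------------------------------
# normality


def _ad_normal_pvalue(a2: float, n: int) -> float:
    """P-value of the Anderson-Darling normality statistic (estimated
    parameters), via the Stephens small-sample correction and the
    D'Agostino piecewise approximation."""
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s ** 2)
    elif a2s > 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s ** 2)
    elif a2s > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s ** 2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s ** 2)
    return float(min(1.0, max(0.0, p)))


def normality_ad(values) -> dict:
    """Anderson-Darling normality gate.

    Returns ``{"statistic": A2, "p": p, "is_normal": p >= 0.05}``.
    Requires n >= 8 non-constant finite values.
    """
    v = _clean(values)
    if len(v) < 8:
        raise StatsError(f"normality untestable: need n >= 8, got {len(v)}")
    if np.ptp(v) == 0:
        raise StatsError("normality untestable: constant sample")
    with warnings.catch_warnings():
        # scipy >= 1.17 asks for an explicit p-value method; only the
        # statistic is used here (the p-value is Stephens/D'Agostino)
        warnings.simplefilter("ignore", FutureWarning)
        a2 = float(sps.anderson(v, dist="norm").statistic)
    p = _ad_normal_pvalue(a2, len(v))
    return {"statistic": a2, "p": p, "is_normal": p >= ALPHA}


# ----------------------------------------------------------------------
# two-group comparison


def compare_groups(a, b) -> dict:
    """Normality-routed two-group test.

    Welch's unpaired t-test when both groups pass the Anderson-Darling
    gate; Mann-Whitney U otherwise (including groups too small for the
    gate, n < 8, where normality cannot be established).
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need n >= 2 in both groups")

    def gate(v):
        try:
            return normality_ad(v)["is_normal"]
        except StatsError:
            return False

    if gate(a) and gate(b):
        res = sps.ttest_ind(a, b, equal_var=False)
        return {"test_used": "welch_t", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"test_used": "mann_whitney", "statistic": float(res.statistic),
            "p": float(res.pvalue)}


# ----------------------------------------------------------------------
# ROC AUC


def _hanley_mcneil_var(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    return (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
            + (n2 - 1) * (q2 - auc ** 2)) / (n1 * n2)


def _wilson_interval(p: float, n_eff: float, alpha: float = ALPHA):
    z = sps.norm.ppf(1 - alpha / 2)
    denom = 1 + z * z / n_eff
    centre = (p + z * z / (2 * n_eff)) / denom
    half = z * math.sqrt(p * (1 - p) / n_eff + z * z / (4 * n_eff ** 2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def roc_auc(values, labels, positive, negate: bool = False) -> dict:
    """ROC AUC of a metric for discriminating the positive (disease) class.

    AUC is the Mann-Whitney U statistic divided by n_pos * n_neg with
    ties counted 0.5 -- the probability that a random positive subject
    scores above a random negative one.  ``negate=True`` flips the score
    sign first; callers use it for metrics whose magnitude *decreases*
    with disease while their sign is positive (e.g. radial strain), so
    that a larger score always means more diseased.

    The confidence interval is a Wilson score interval on the AUC with an
    effective sample size n_eff = AUC*(1-AUC)/Var_HM, where Var_HM is the
    Hanley-McNeil AUC variance; with perfect separation (zero variance)
    n_eff falls back to n_pos * n_neg.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if negate:
        v = -v
    pos = v[lab == positive]
    neg = v[lab != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("ROC needs both classes present")
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))
    var = _hanley_mcneil_var(auc, len(pos), len(neg))
    n_eff = auc * (1 - auc) / var if var > 0 else len(pos) * len(neg)
    lo, hi = _wilson_interval(auc, n_eff)
    return {"auc": auc, "ci_low": lo, "ci_high": hi}


# ----------------------------------------------------------------------
# correlation


def spearman_corr(x, y, family_size: int = 1) -> dict:
    """Spearman rank correlation with Bonferroni-adjusted p-value.

    Pairs with a missing value in either variable are dropped.  The
    family size is the number of cells in the reported correlation table
    (strain-kind x region x covariate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise StatsError(f"need >= 5 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant variable: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p),
            "p_adjusted": float(min(1.0, family_size * p))}


# ----------------------------------------------------------------------
# multi-group


def multigroup_compare(groups: dict) -> pd.DataFrame:
    """One-way ANOVA with Tukey-HSD-adjusted pairwise comparisons.

    ``groups`` maps label -> sample.  Returns one row per pair with the
    adjusted p-value; the overall ANOVA F and p are in ``df.attrs``.
    """
    labels = list(groups)
    samples = [_clean(groups[k]) for k in labels]
    if len(labels) < 2:
        raise StatsError("need >= 2 groups")
    for k, s in zip(labels, samples):
        if len(s) < 2:
            raise StatsError(f"group {k!r} needs n >= 2")
    if all(np.ptp(s) == 0 for s in samples):
        raise StatsError("zero pooled variance: comparisons undefined")
    f, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adjusted": float(hsd.pvalue[i, j]),
            })
    out = pd.DataFrame(rows)
    out.attrs["anova_F"] = float(f)
    out.attrs["anova_p"] = float(p)
    return out


# ----------------------------------------------------------------------
# cohort-table drivers


#: Expected healthy-direction sign per strain kind: metrics whose healthy
#: value is negative (Ecc, Ell, Ea and their rates) already score disease
#: higher; positive-signed metrics (Err) are negated before ROC.
METRIC_SIGNS = {"ecc": -1, "ell": -1, "ea": -1, "err": +1}


def _metric_sign(metric: str) -> int:
    kind = metric.split("_", 1)[0].lower()
    return METRIC_SIGNS.get(kind, -1)


def compare_cohort(table: pd.DataFrame, metrics, group_col: str = "group",
                   positive: str = "disease") -> pd.DataFrame:
    """Two-group comparison + ROC for each metric column of a cohort table."""
    rows = []
    for m in metrics:
        a = table.loc[table[group_col] != positive, m]
        b = table.loc[table[group_col] == positive, m]
        cmp_res = compare_groups(a, b)
        roc = roc_auc(table[m], table[group_col], positive,
                      negate=_metric_sign(m) > 0)
        rows.append({"metric": m, **cmp_res, **roc})
    return pd.DataFrame(rows)


def correlate_cohort(table: pd.DataFrame, metrics, covariates) -> pd.DataFrame:
    """Spearman correlations of metrics against covariates, Bonferroni-
    corrected over the full metric x covariate family."""
    family = len(metrics) * len(covariates)
    rows = []
    for m in metrics:
        for c in covariates:
            res = spearman_corr(table[m], table[c], family_size=family)
            rows.append({"metric": m, "covariate": c, **res})
    return pd.DataFrame(rows)
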