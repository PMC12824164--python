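"""Performance and clinical-utility evaluation suite.

ROC/AUC with DeLong variance and paired DeLong comparison, confusion-matrix
metrics at a frozen threshold (Youden on the training split by default),
quantile-binned calibration, decision-curve net benefit, rater comparison by
operating-point matching with exact McNemar, Cohen's kappa with qualitative
bands, and two-way random-effects ICC(2,1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

log = logging.getLogger(__name__)

KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (cases) and V01 (controls) and the AUC."""
    y = np.asarray(labels).astype(int)
    pos = np.asarray(scores, float)[y == 1]
    neg = np.asarray(scores, float)[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # per-case placement
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per-control placement
    return auc, v10, v01


def auc_delong(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """AUC (Mann-Whitney with tie credit), DeLong variance and normal 95% CI."""
    auc, v10, v01 = _delong_components(scores, labels)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    se = np.sqrt(var)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return float(auc), float(var), ci


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong z and two-sided p for the AUC difference of two models
    scored on the same samples."""
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# threshold metrics, calibration, decision curve


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cut maximising sensitivity + specificity − 1 (ties → lower cut)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    cuts = np.unique(s)
    best, best_j = cuts[0], -np.inf
    for c in cuts:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best, best_j = c, j
    return float(best)


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / PPV / NPV at ``score >= threshold``."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = tp + tn + fp + fn
    return {
        "threshold": float(threshold),
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def calibration_curve(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Quantile-binned calibration: mean prediction vs observed event rate.

    Tied scores that collapse bin edges merge bins (logged).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    if len(s) < n_bins:
        raise ValueError("need at least n_bins samples")
    if np.ptp(s) == 0:
        # constant scores: a single bin at (score, prevalence)
        return pd.DataFrame(
            {"mean_predicted": [s.mean()], "observed_rate": [y.mean()], "count": [len(y)]}
        )
    bins = pd.qcut(s, q=n_bins, duplicates="drop")
    if bins.categories.size < n_bins:
        log.info("calibration: merged %d tied bins", n_bins - bins.categories.size)
    df = pd.DataFrame({"score": s, "label": y, "bin": bins})
    out = df.groupby("bin", observed=True).agg(
        mean_predicted=("score", "mean"),
        observed_rate=("label", "mean"),
        count=("label", "size"),
    )
    return out.reset_index(drop=True)


def decision_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit NB(t) = TP/n − FP/n · t/(1−t) over a threshold grid,
    with treat-all and treat-none reference policies."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        pred = s >= t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        odds = t / (1 - t)
        rows.append(
            {
                "threshold": t,
                "net_benefit": tp - fp * odds,
                "treat_all": prev - (1 - prev) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model vs rater


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p from discordant counts (binomial tails)."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    p = 2 * stats.binom.cdf(k, n, 0.5)
    # subtract the doubled midpoint when b == c (both tails share it)
    if b == c:
        p -= stats.binom.pmf(k, n, 0.5)
    return float(min(p, 1.0))


def operating_point_match(
    scores: np.ndarray,
    labels: np.ndarray,
    rater_calls: np.ndarray,
    match: str = "sensitivity",
) -> dict:
    """Compare the model with a rater at a matched operating point.

    The model threshold is chosen so the matched metric is the smallest value
    >= the rater's; the complementary metric is then compared and an exact
    McNemar test on the discordant pairs (model call vs rater call against
    truth-agnostic calls) quantifies disagreement.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    r = np.asarray(rater_calls).astype(int)
    rater = threshold_metrics(r.astype(float), y, 0.5)
    target = rater[match]
    candidates = []
    for c in np.unique(s):
        m = threshold_metrics(s, y, c)
        if m[match] >= target:
            candidates.append(m)
    if not candidates:
        return {"matchable": False, "rater": rater}
    other = "specificity" if match == "sensitivity" else "sensitivity"
    # smallest attainable matched value >= the rater's; among ties take the
    # best complementary metric (the efficient point on the ROC staircase)
    floor = min(d[match] for d in candidates)
    m = max((d for d in candidates if d[match] == floor), key=lambda d: d[other])
    model_calls = (s >= m["threshold"]).astype(int)
    b = int(((model_calls == 1) & (r == 0)).sum())
    c = int(((model_calls == 0) & (r == 1)).sum())
    return {
        "matchable": True,
        "matched_on": match,
        "threshold": m["threshold"],
        "rater": rater,
        "model": m,
        "delta_" + other: m[other] - rater[other],
        "mcnemar_b": b,
        "mcnemar_c": c,
        "mcnemar_p": mcnemar_exact(b, c),
    }


def kappa_band(kappa: float) -> str:
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "almost perfect"


def cohen_kappa(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, str]:
    """Cohen's kappa with the five-level qualitative band (closed upper edges)."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if len(a) != len(b):
        raise ValueError("call vectors must align")
    if len(np.unique(np.concatenate([a, b]))) < 2:
        # both raters constant and identical: perfect agreement by convention
        log.info("kappa: degenerate single-category table, returning 1.0")
        return 1.0, "almost perfect"
    k = float(cohen_kappa_score(a, b))
    return k, kappa_band(k)


def icc_agreement(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is items × raters.  Variance components come from the
    two-way ANOVA mean squares.
    """
    X = np.asarray(measurements, float)
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 items")
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    sse = ((X - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)
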