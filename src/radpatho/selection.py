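"""Four-stage feature-selection cascade and inter-site stability screen.

The cascade mirrors common radiomics practice: z-score normalisation fitted
on the training split, a one-way ANOVA significance filter, a greedy Spearman
redundancy prune (|rho| >= 0.8 keeps one of each correlated pair), a Boruta
all-relevant screen against shadow features, and finally an L1-penalised
logistic model whose nonzero coefficients define the selected subset.  The
survivors of each stage are nested by construction.

The signal-to-noise (SNR) screen quantifies per-feature biological variance
relative to inter-site variance with a one-way random-effects decomposition;
SNR >= 2 flags a feature as highly reliable across institutions, 1–2 as
moderately reliable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Per-stage survivors plus diagnostics; survivor lists are nested."""

    anova_f: pd.Series = field(default_factory=pd.Series)
    anova_p: pd.Series = field(default_factory=pd.Series)
    anova_survivors: list[str] = field(default_factory=list)
    pruned_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    prune_survivors: list[str] = field(default_factory=list)
    boruta_decisions: dict[str, str] = field(default_factory=dict)
    boruta_hits: dict[str, int] = field(default_factory=dict)
    boruta_survivors: list[str] = field(default_factory=list)
    lasso_coefficients: pd.Series = field(default_factory=pd.Series)
    lasso_C: float = float("nan")
    selected: list[str] = field(default_factory=list)

    def assert_nested(self) -> None:
        a, p, b, s = (
            set(self.anova_survivors),
            set(self.prune_survivors),
            set(self.boruta_survivors),
            set(self.selected),
        )
        assert s <= b <= p <= a, "survivor sets must be nested"


class ZScorer:
    """Column-wise standardisation fitted on training rows (sample SD, n-1).

    Constant training columns are dropped with a warning rather than divided
    by zero.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None
        self.dropped_: list[str] = []

    def fit(self, block: pd.DataFrame) -> "ZScorer":
        sd = block.std(ddof=1)
        self.dropped_ = sd.index[(sd == 0) | sd.isna()].tolist()
        if self.dropped_:
            warnings.warn(f"dropping constant features: {self.dropped_}")
        keep = sd.index.difference(self.dropped_, sort=False)
        self.mean_ = block[keep].mean()
        self.sd_ = sd[keep]
        return self

    def transform(self, block: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("ZScorer not fitted")
        return (block[self.mean_.index] - self.mean_) / self.sd_


def zscore(
    block: pd.DataFrame, train_index: pd.Index | None = None
) -> tuple[pd.DataFrame, ZScorer]:
    """Standardise a block with parameters estimated on ``train_index`` rows."""
    train = block if train_index is None else block.loc[train_index]
    scaler = ZScorer().fit(train)
    return scaler.transform(block), scaler


def anova_filter(
    block: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.Series, pd.Series]:
    """Keep features whose one-way ANOVA p-value is below ``alpha``.

    For two groups this is equivalent to the pooled-variance t-test
    (F = t^2).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("each class needs at least 2 samples")
    F, p = f_classif(block.to_numpy(), y)
    F = pd.Series(F, index=block.columns)
    p = pd.Series(p, index=block.columns)
    return p.index[p < alpha].tolist(), F, p


def spearman_prune(
    block: pd.DataFrame,
    anova_f: pd.Series,
    threshold: float = 0.8,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy redundancy prune over features ordered by descending ANOVA F.

    A feature is dropped when its |Spearman rho| with any already-kept
    feature reaches ``threshold``; keeping the larger-F member makes the rule
    deterministic and favours label-relevant features.
    """
    cols = anova_f.loc[block.columns].sort_values(ascending=False).index.tolist()
    if len(cols) < 2:
        return list(cols), []
    rho = block[cols].corr(method="spearman").to_numpy()
    kept: list[int] = []
    pruned: list[tuple[str, str, float]] = []
    for i in range(len(cols)):
        clash = [k for k in kept if abs(rho[i, k]) >= threshold]
        if clash:
            k = clash[0]
            pruned.append((cols[i], cols[k], float(rho[i, k])))
        else:
            kept.append(i)
    return [cols[k] for k in kept], pruned


def boruta(
    block: pd.DataFrame,
    labels: np.ndarray,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 100,
    keep_tentative: bool = False,
) -> tuple[dict[str, str], dict[str, int]]:
    """All-relevant screen against shadow (permuted-copy) features.

    Each iteration appends a column-permuted shadow copy of every feature,
    fits a random forest, and scores a "hit" for each real feature whose
    importance exceeds the maximum shadow importance.  Decisions are by a
    two-sided binomial test of the hit count against Binomial(max_iter, 0.5)
    with Bonferroni correction: upper-tail significant → confirmed,
    lower-tail significant → rejected, otherwise tentative.  All features
    stay in play for the full ``max_iter`` iterations.
    """
    y = np.asarray(labels)
    if min(np.bincount(y.astype(int))) < 5:
        raise ValueError("need at least 5 samples per class")
    rng = np.random.default_rng(seed)
    X = block.to_numpy()
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    for it in range(max_iter):
        shadow = X.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=5,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(np.hstack([X, shadow]), y)
        imp = rf.feature_importances_
        hits += imp[:p] > imp[p:].max()
    thr = alpha / p  # Bonferroni
    decisions = {}
    for j, name in enumerate(block.columns):
        upper = stats.binom.sf(hits[j] - 1, max_iter, 0.5)
        lower = stats.binom.cdf(hits[j], max_iter, 0.5)
        if upper < thr:
            decisions[name] = "confirmed"
        elif lower < thr:
            decisions[name] = "rejected"
        else:
            decisions[name] = "tentative"
    if keep_tentative:
        for k, v in decisions.items():
            if v == "tentative":
                decisions[k] = "confirmed"
    return decisions, dict(zip(block.columns, hits.tolist()))


def lasso_select(
    block: pd.DataFrame,
    labels: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    Cs: int = 20,
) -> tuple[list[str], pd.Series, float]:
    """L1-penalised logistic selection at the CV-deviance-optimal penalty.

    Returns features with nonzero coefficient magnitude.  An empty selection
    (heavy penalty everywhere) is returned with a warning; callers fall back
    to the Boruta-confirmed set.
    """
    if block.shape[1] < 1:
        return [], pd.Series(dtype=float), float("nan")
    y = np.asarray(labels)
    n_folds = min(n_folds, int(min(np.bincount(y.astype(int)))))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        l1_ratios=(1,),
        solver="liblinear",
        scoring="neg_log_loss",
        random_state=seed,
        max_iter=2000,
        use_legacy_attributes=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter at large C
        model.fit(block.to_numpy(), y)
    coef = pd.Series(model.coef_.ravel(), index=block.columns)
    selected = coef.index[coef.abs() > 0].tolist()
    if not selected:
        warnings.warn("LASSO selected no features; falling back upstream")
    return selected, coef, float(model.C_[0])


def run_cascade(
    block: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    prune_threshold: float = 0.8,
    boruta_max_iter: int = 100,
    boruta_trees: int = 100,
    lasso_folds: int = 10,
    seed: int = 0,
) -> SelectionReport:
    """ANOVA → Spearman prune → Boruta → LASSO on one (standardised) block."""
    rep = SelectionReport()
    survivors, rep.anova_f, rep.anova_p = anova_filter(block, labels, alpha)
    rep.anova_survivors = survivors
    if not survivors:
        return rep
    rep.prune_survivors, rep.pruned_pairs = spearman_prune(
        block[survivors], rep.anova_f.loc[survivors], prune_threshold
    )
    if not rep.prune_survivors:
        return rep
    rep.boruta_decisions, rep.boruta_hits = boruta(
        block[rep.prune_survivors],
        labels,
        max_iter=boruta_max_iter,
        seed=seed,
        n_estimators=boruta_trees,
    )
    rep.boruta_survivors = [
        f for f in rep.prune_survivors if rep.boruta_decisions[f] == "confirmed"
    ]
    if not rep.boruta_survivors:
        rep.selected = []
        rep.assert_nested()
        return rep
    selected, rep.lasso_coefficients, rep.lasso_C = lasso_select(
        block[rep.boruta_survivors], labels, n_folds=lasso_folds, seed=seed
    )
    rep.selected = selected if selected else list(rep.boruta_survivors)
    rep.assert_nested()
    return rep


# ---------------------------------------------------------------------------
# inter-site SNR stability screen


def snr(
    block: pd.DataFrame,
    sites: pd.Series | np.ndarray,
    eps: float = 1e-12,
) -> pd.DataFrame:
    """Per-feature signal-to-noise ratio across sites.

    One-way random-effects decomposition with site as the grouping factor:
    the between-site variance component sigma2_site comes from the
    between-site mean square, the biological (signal) variance is the
    residual within-site variance.  ``SNR = sqrt(sigma2_within /
    sigma2_site)``; negative between-site component estimates are truncated
    at ``eps`` (SNR then reflects an effectively site-free feature).

    Returns a frame with columns signal_sd, site_sd, snr, reliable
    (SNR >= 2) and moderate (1 <= SNR < 2).
    """
    sites = pd.Series(np.asarray(sites), index=block.index)
    levels = sites.unique()
    if len(levels) < 2:
        raise ValueError("SNR requires at least 2 sites")
    counts = sites.value_counts()
    if counts.min() < 2:
        raise ValueError("each site needs at least 2 patients")
    N = len(block)
    k = len(levels)
    X = block.to_numpy(float)
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for s in levels:
        rows = X[(sites == s).to_numpy()]
        ss_between += len(rows) * (rows.mean(axis=0) - grand) ** 2
        ss_within += ((rows - rows.mean(axis=0)) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (counts**2).sum() / N) / (k - 1)  # effective group size
    var_site = np.maximum((ms_between - ms_within) / n0, eps)
    ratio = np.sqrt(ms_within / var_site)
    out = pd.DataFrame(
        {
            "signal_sd": np.sqrt(ms_within),
            "site_sd": np.sqrt(var_site),
            "snr": ratio,
            "reliable": ratio >= 2,
            "moderate": (ratio >= 1) & (ratio < 2),
        },
        index=block.columns,
    )
    return out
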