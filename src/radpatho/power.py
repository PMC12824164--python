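"""Feature–pathway annotation and post-hoc correlation power analysis.

:func:`annotate_features` links each selected imaging feature to the
per-sample activity scores of significantly enriched pathways by Pearson
correlation with a joint Benjamini–Hochberg family (FDR < 0.1), keeps the
top-5 pathways per feature ranked by |r|, and joins an optional
pathway→biological-category map.

:func:`correlation_power` reproduces the classic post-hoc power
approximation for a two-sided Pearson correlation test (the algorithm behind
R's ``pwr.r.test``): the critical correlation is mapped through the t
distribution at n−2 degrees of freedom and compared with the bias-corrected
Fisher transform of the observed r on the sqrt(n−3) scale.
:func:`mdcc` inverts it to the minimum detectable correlation coefficient at
a target power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from radpatho.enrichment import bh_fdr


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Achieved power of the two-sided Pearson correlation test.

    With t_c the two-sided critical value of t(n−2), the critical
    correlation is r_c = sqrt(t_c² / (t_c² + n − 2)).  The observed effect on
    the Fisher scale uses the bias-corrected transform
    z_r = atanh(r) + r / (2(n−1)) and

        power = Φ((z_r − z_c)·sqrt(n−3)) + Φ((−z_r − z_c)·sqrt(n−3)).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < abs(r) < 1:
        raise ValueError("require 0 < |r| < 1")
    tc = stats.t.ppf(1 - alpha / 2, n - 2)
    rc = np.sqrt(tc**2 / (tc**2 + n - 2))
    zr = np.arctanh(r) + r / (2 * (n - 1))
    zc = np.arctanh(rc)
    s = np.sqrt(n - 3)
    return float(stats.norm.cdf((zr - zc) * s) + stats.norm.cdf((-zr - zc) * s))


def mdcc(n: int, alpha: float = 0.05, target_power: float = 0.8) -> float:
    """Minimum detectable correlation at the target power (bisection)."""
    if n < 4:
        raise ValueError("need n >= 4")
    f = lambda r: correlation_power(r, n, alpha) - target_power
    lo, hi = 1e-9, 1 - 1e-9
    if f(hi) < 0:
        raise ValueError("target power unreachable for this n")
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def load_category_map(path) -> dict[str, str]:
    """Two-column CSV (pathway, category) → mapping for annotate_features."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("category map needs two columns: pathway, category")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def annotate_features(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    category_map: dict[str, str] | None = None,
    fdr_cut: float = 0.1,
    top_k: int = 5,
) -> pd.DataFrame:
    """Top-``top_k`` pathway annotation per feature by Pearson correlation.

    All (feature, pathway) pairs form one BH family; per feature, pairs with
    FDR < ``fdr_cut`` are ranked by |r| and the strongest ``top_k`` kept.
    Returns the full table with columns feature, pathway, r, p, fdr, rank
    (NaN outside the reported top rows) and category.
    """
    common = features.index.intersection(scores.index)
    if len(common) < 4:
        raise ValueError("need at least 4 shared samples")
    F = features.loc[common]
    S = scores.loc[common]
    rows = []
    for f in F.columns:
        x = F[f].to_numpy(float)
        for p_name in S.columns:
            ysc = S[p_name].to_numpy(float)
            if np.std(x) == 0 or np.std(ysc) == 0:
                rows.append({"feature": f, "pathway": p_name, "r": np.nan, "p": np.nan})
                continue
            res = stats.pearsonr(x, ysc)
            rows.append(
                {
                    "feature": f,
                    "pathway": p_name,
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table["rank"] = np.nan
    for f, grp in table.groupby("feature"):
        hits = grp[grp["fdr"] < fdr_cut].sort_values("r", key=abs, ascending=False)
        for rank, idx in enumerate(hits.index[:top_k], start=1):
            table.loc[idx, "rank"] = rank
    cmap = category_map or {}
    table["category"] = table["pathway"].map(lambda s: cmap.get(s, "unmapped"))
    return table


def power_report(
    annotation: pd.DataFrame, n: int, alpha: float = 0.05, target_power: float = 0.8
) -> pd.DataFrame:
    """Achieved power per reported annotation row plus the MDCC for this n."""
    rows = annotation[annotation["rank"].notna()].copy()
    rows["power"] = [
        correlation_power(r, n, alpha) if 0 < abs(r) < 1 else np.nan
        for r in rows["r"]
    ]
    rows["mdcc"] = mdcc(n, alpha, target_power)
    return rows
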