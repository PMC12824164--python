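"""Pathway machinery: over-representation, per-sample set activity, GSEA.

* :func:`ora` — upper-tail hypergeometric over-representation of a gene
  module in each gene set, Benjamini–Hochberg corrected across sets
  (significant at FDR < 0.05);
* :func:`ssgsea_score` — per-sample single-sample enrichment scores (rank
  weighted Kolmogorov–Smirnov running sum, weight exponent 0.25, rescaled by
  the global score range), standing in for per-sample set-activity scoring;
* :func:`compare_pathways` — per-pathway two-sided Mann–Whitney U between
  grade groups with BH correction;
* :func:`gsea` — two-class GSEA with a signal-to-noise ranking metric,
  weighted ES (p = 1), phenotype-permutation null, NES normalised by the
  same-sign null mean, and sign-pooled FDR.

Gene sets are read and written in the plain-text GMT convention
(name, description, genes, tab separated).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, float)
    mask = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# over-representation


def ora(
    module_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a module in each gene set.

    p = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|module|); BH-adjusted across sets.
    """
    uni = set(universe)
    module = set(module_genes) & uni
    if not module:
        raise ValueError("module has no genes in the universe")
    N = len(uni)
    rows = []
    for name, genes in gene_sets.items():
        in_uni = set(genes) & uni
        if not in_uni:
            rows.append({"set": name, "overlap": 0, "set_size": 0, "p": np.nan})
            continue
        overlap = len(module & in_uni)
        p = stats.hypergeom.sf(overlap - 1, N, len(in_uni), len(module))
        rows.append(
            {"set": name, "overlap": overlap, "set_size": len(in_uni), "p": float(p)}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_cut
    return out


# ---------------------------------------------------------------------------
# single-sample scores


def _ssgsea_one(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Integrated running-sum difference for one sample.

    ``order`` sorts genes by decreasing expression; in-set genes contribute
    their expression rank to the power ``alpha``, out-of-set genes uniformly.
    """
    n = len(order)
    ranks = np.arange(n, 0, -1, dtype=float)  # n .. 1, top gene gets n
    w = ranks**alpha
    members = in_set[order]
    w_in = np.where(members, w, 0.0)
    p_in = np.cumsum(w_in)
    if p_in[-1] == 0:
        return 0.0
    p_in /= p_in[-1]
    n_out = (~members).sum()
    if n_out == 0:
        return 0.0
    p_out = np.cumsum(np.where(members, 0.0, 1.0)) / n_out
    return float((p_in - p_out).sum() / n)


def ssgsea_score(
    mat: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
    min_size: int = 2,
    normalize: bool = True,
) -> pd.DataFrame:
    """Samples × pathways activity matrix (ssGSEA-style scores).

    Sets with fewer than ``min_size`` genes matched to the matrix are
    skipped with a warning.  With ``normalize=True`` all scores are divided
    by the global score range, the usual cross-sample normalisation.
    """
    genes = mat.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    masks = {}
    for name, members in gene_sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < min_size:
            warnings.warn(f"gene set {name!r}: <{min_size} genes matched, skipped")
            continue
        m = np.zeros(len(genes), dtype=bool)
        m[idx] = True
        masks[name] = m
    X = mat.to_numpy()
    scores = np.zeros((mat.shape[1], len(masks)))
    for s in range(mat.shape[1]):
        order = np.argsort(-X[:, s], kind="stable")
        for j, m in enumerate(masks.values()):
            scores[s, j] = _ssgsea_one(order, m, alpha)
    out = pd.DataFrame(scores, index=mat.columns, columns=list(masks))
    if normalize and out.size:
        rng_span = out.to_numpy().max() - out.to_numpy().min()
        if rng_span > 0:
            out = out / rng_span
    return out


def compare_pathways(
    scores: pd.DataFrame, labels: np.ndarray, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Per-pathway two-sided Mann–Whitney U between grade groups, BH FDR."""
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 samples per group")
    rows = []
    for col in scores.columns:
        a = scores.loc[y == 1, col].to_numpy()
        b = scores.loc[y == 0, col].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append({"set": col, "U": np.nan, "p": 1.0})
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"set": col, "U": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_cut
    return out


# ---------------------------------------------------------------------------
# GSEA


def _signal_to_noise(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b = X[:, y == 1], X[:, y == 0]
    sd = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    sd = np.where(sd == 0, 1e-12, sd)
    return (a.mean(axis=1) - b.mean(axis=1)) / sd


def _es(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted KS enrichment score (weight = |metric|, p = 1)."""
    order = np.argsort(-metric, kind="stable")
    members = in_set[order]
    n_out = (~members).sum()
    if n_out == 0 or members.sum() == 0:
        return 0.0
    w = np.abs(metric[order]) * members
    if w.sum() == 0:
        w = members.astype(float)
    p_hit = np.cumsum(w) / w.sum()
    p_miss = np.cumsum(~members) / n_out
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea(
    mat: pd.DataFrame,
    labels: np.ndarray,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Two-class GSEA with phenotype permutation.

    Genes are ranked by signal-to-noise between the groups; the enrichment
    score is the maximum deviation of the weighted running sum.  NES divides
    ES by the mean |null ES| of the same sign; the nominal p is the same-sign
    null tail; FDR follows the positive/negative pooling rule (fraction of
    pooled same-sign null NES at least as extreme, divided by the fraction of
    observed same-sign NES at least as extreme).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: FDR estimates are unstable")
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 samples per group")
    genes = mat.index.to_numpy()
    X = mat.to_numpy()
    masks = {}
    for name, members in gene_sets.items():
        m = np.isin(genes, members)
        if m.sum() < min_size:
            continue
        masks[name] = m  # a full-universe set stays and scores ES = 0
    metric = _signal_to_noise(X, y)
    obs = {name: _es(metric, m) for name, m in masks.items()}
    rng = np.random.default_rng(seed)
    null = {name: np.empty(n_perm) for name in masks}
    for p in range(n_perm):
        yp = rng.permutation(y)
        mp = _signal_to_noise(X, yp)
        for name, m in masks.items():
            null[name][p] = _es(mp, m)
    rows = []
    for name, es in obs.items():
        nl = null[name]
        same = nl[np.sign(nl) == np.sign(es)] if es != 0 else nl
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and not np.isnan(denom) else 0.0
        if len(same):
            pval = (np.abs(same) >= abs(es)).mean()
        else:
            pval = 1.0
        rows.append({"set": name, "ES": es, "NES": float(nes), "p": float(pval)})
    out = pd.DataFrame(rows).set_index("set")
    # sign-pooled FDR over normalised null scores
    null_nes = []
    for name in masks:
        nl = null[name]
        for sign in (1, -1):
            part = nl[np.sign(nl) == sign]
            if len(part):
                null_nes.extend(part / np.abs(part).mean())
    null_nes = np.asarray(null_nes)
    fdrs = []
    obs_nes = out["NES"].to_numpy()
    for nes in obs_nes:
        if nes == 0 or len(null_nes) == 0:
            fdrs.append(1.0)
            continue
        if nes > 0:
            num = (null_nes >= nes).mean() if len(null_nes) else 1.0
            den = (obs_nes >= nes).mean()
        else:
            num = (null_nes <= nes).mean()
            den = (obs_nes <= nes).mean()
        fdrs.append(min(1.0, num / max(den, 1e-12)))
    out["fdr"] = fdrs
    return out
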