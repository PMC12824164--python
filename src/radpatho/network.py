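"""Weighted gene co-expression network analysis (WGCNA-style).

Pipeline: FPKM→TPM conversion, log2 transform with per-batch location-scale
alignment and MAD-based gene filtering; soft-threshold selection by
scale-free topology fit (signed R² >= 0.85); unsigned adjacency
``|cor|^beta`` and topological overlap matrix (TOM); average-linkage
clustering of 1−TOM with a static height cut, size filter and eigengene
merging (merge when eigengene dissimilarity < mergeCutHeight); module
eigengenes as sign-oriented first principal components; module–trait
Spearman correlation; permutation module preservation (Zsummary, medianRank)
between a reference and a test expression matrix; and hub-gene selection at
|MM| > 0.80 and GS > 0.20.

This is a compact reimplementation of the ideas, not a numerical clone of
the reference R package: the dynamic tree cut is replaced by the documented
static-cut + merge procedure and preservation uses a two-statistic composite
(density + connectivity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

GREY = "grey"
#: module label palette, in detection (size) order
_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)


@dataclass
class NetworkParams:
    powers: tuple[int, ...] = tuple(range(1, 21))
    rsquared_cut: float = 0.85
    min_module_size: int = 30
    merge_cut_height: float = 0.35
    static_cut_height: float = 0.99
    fallback_power: int = 6  # recommended unsigned default when no power fits
    min_mean_k: float = 1.0  # powers below this mean connectivity are degenerate


@dataclass
class ModuleSet:
    """Gene→module assignment with eigengenes and per-gene statistics."""

    labels: pd.Series  # gene -> module color (grey = unassigned)
    eigengenes: pd.DataFrame  # samples × modules, unit variance
    kme: pd.DataFrame  # genes × modules module-membership correlations
    gs: pd.Series = field(default_factory=pd.Series)  # |cor(gene, trait)|
    beta: int = 6

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def genes_in(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()


def fpkm_to_tpm(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rescaling: TPM_g = FPKM_g / Σ_g FPKM × 1e6."""
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total FPKM")
    return mat / totals * 1e6


def preprocess(
    mat: pd.DataFrame,
    batch: pd.Series | None = None,
    top_n: int = 5000,
    log_transform: bool = True,
) -> pd.DataFrame:
    """log2(x+1), per-batch location-scale alignment, top-``top_n`` MAD filter.

    Batch alignment centres and rescales each gene within batch to the
    pooled per-gene mean/SD (a simple location-scale surrogate for
    empirical-Bayes batch correction).  Single-sample batches are centred
    only.
    """
    X = np.log2(mat + 1.0) if log_transform else mat.copy()
    if batch is not None:
        batch = pd.Series(np.asarray(batch), index=X.columns)
        pooled_mean = X.mean(axis=1)
        pooled_sd = X.std(axis=1, ddof=1).replace(0, 1.0)
        adjusted = X.copy()
        for b in batch.unique():
            cols = batch.index[batch == b]
            sub = X[cols]
            mu = sub.mean(axis=1)
            if len(cols) < 2:
                warnings.warn(f"batch {b!r} has one sample; centring only")
                adjusted[cols] = sub.sub(mu, axis=0).add(pooled_mean, axis=0)
                continue
            sd = sub.std(axis=1, ddof=1).replace(0, 1.0)
            z = sub.sub(mu, axis=0).div(sd, axis=0)
            adjusted[cols] = z.mul(pooled_sd, axis=0).add(pooled_mean, axis=0)
        X = adjusted
    mad = (X.sub(X.median(axis=1), axis=0)).abs().median(axis=1)
    keep = mad.sort_values(ascending=False).index[: min(top_n, len(mad))]
    return X.loc[keep]


def _adjacency(mat: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta over genes (rows); zero diagonal."""
    a = np.abs(np.corrcoef(mat.to_numpy())) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of log10 p(k) vs log10 mean-k over connectivity bins."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    # equal-width connectivity bins, the WGCNA convention
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        members = k[idx == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / len(k)))
    if len(xs) < 3:
        return 0.0
    res = stats.linregress(xs, ys)
    if np.isnan(res.rvalue):
        return 0.0
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    mat: pd.DataFrame, params: NetworkParams | None = None
) -> tuple[int, pd.DataFrame]:
    """Smallest power reaching the scale-free fit cut at non-degenerate
    connectivity.

    Powers whose mean connectivity falls below ``min_mean_k`` are excluded
    (at such powers the log-log fit is trivially good because the network has
    effectively dissolved); if no remaining power reaches ``rsquared_cut``
    the standard unsigned default ``fallback_power`` is used with a warning.
    """
    params = params or NetworkParams()
    if len(mat) < 30:
        raise ValueError("need at least 30 genes")
    corr = np.abs(np.corrcoef(mat.to_numpy()))
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in params.powers:
        k = (corr**beta).sum(axis=1)
        rows.append({"power": beta, "fit": _scale_free_fit(k), "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    ok = table[(table["fit"] >= params.rsquared_cut) & (table["mean_k"] >= params.min_mean_k)]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = params.fallback_power
        warnings.warn(
            f"no power reaches scale-free fit {params.rsquared_cut}; "
            f"falling back to the unsigned default beta={beta}"
        )
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij).

    ``adjacency`` must have a zero diagonal; the TOM diagonal is set to 1.
    """
    a = adjacency
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(sub: pd.DataFrame) -> np.ndarray:
    """Sign-oriented, unit-variance first PC of a genes × samples submatrix."""
    Z = stats.zscore(sub.to_numpy(), axis=1, ddof=1)
    Z = np.nan_to_num(Z)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    ev = vt[0]
    # orient so member genes correlate positively on average
    mean_cor = np.mean([np.corrcoef(row, ev)[0, 1] for row in Z])
    if mean_cor < 0:
        ev = -ev
    return ev / ev.std(ddof=1)


def detect_modules(
    mat: pd.DataFrame,
    beta: int,
    params: NetworkParams | None = None,
    trait: np.ndarray | None = None,
) -> ModuleSet:
    """Cluster 1−TOM, cut statically, filter small clusters, merge by ME.

    Initial clusters come from cutting the average-linkage dendrogram at the
    fixed dissimilarity ``static_cut_height`` (genes merging only near 1 are
    background); clusters below ``min_module_size`` go grey.  Modules whose
    eigengene dissimilarity 1 − cor(ME_a, ME_b) falls below
    ``merge_cut_height`` are merged iteratively (closest pair first).
    """
    params = params or NetworkParams()
    genes = mat.index
    a = _adjacency(mat, beta)
    tom = tom_similarity(a)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=params.static_cut_height, criterion="distance")
    labels = pd.Series([GREY] * len(genes), index=genes)
    clusters = pd.Series(raw, index=genes)
    sizes = clusters.value_counts()
    kept = sizes.index[sizes >= params.min_module_size]
    if len(kept) == 0:
        warnings.warn("no cluster reaches min_module_size; all genes grey")
        return ModuleSet(
            labels=labels,
            eigengenes=pd.DataFrame(index=mat.columns),
            kme=pd.DataFrame(index=genes),
            beta=beta,
        )
    # name modules by size order with the conventional color palette
    for color, cid in zip(_COLORS, sizes.loc[kept].sort_values(ascending=False).index):
        labels[clusters == cid] = color
    member_modules = [m for m in labels.unique() if m != GREY]
    mes = {m: _eigengene(mat.loc[labels == m]) for m in member_modules}

    # iterative closest-pair eigengene merge
    while len(mes) > 1:
        names = list(mes)
        me_mat = np.vstack([mes[m] for m in names])
        cor = np.corrcoef(me_mat)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= params.merge_cut_height:
            break
        keep, drop = (names[i], names[j])
        if (labels == drop).sum() > (labels == keep).sum():
            keep, drop = drop, keep
        log.info("merging module %s into %s (ME cor %.3f)", drop, keep, cor[i, j])
        labels[labels == drop] = keep
        del mes[drop]
        mes[keep] = _eigengene(mat.loc[labels == keep])

    me_df = pd.DataFrame(mes, index=mat.columns)
    Z = stats.zscore(mat.to_numpy(), axis=1, ddof=1)
    kme = pd.DataFrame(
        {
            m: Z @ stats.zscore(me_df[m].to_numpy(), ddof=1) / (Z.shape[1] - 1)
            for m in me_df.columns
        },
        index=genes,
    )
    ms = ModuleSet(labels=labels, eigengenes=me_df, kme=kme, beta=beta)
    if trait is not None:
        t = np.asarray(trait, float)
        tz = (t - t.mean()) / t.std(ddof=1)
        ms.gs = pd.Series(np.abs(Z @ tz / (Z.shape[1] - 1)), index=genes)
    return ms


def module_trait(ms: ModuleSet, trait: np.ndarray) -> pd.DataFrame:
    """Spearman correlation of each module eigengene with the trait."""
    rows = []
    for m in ms.eigengenes.columns:
        ev = ms.eigengenes[m].to_numpy()
        if np.std(ev) == 0:
            rows.append({"module": m, "r": np.nan, "p": np.nan, "significant": False})
            continue
        res = stats.spearmanr(ev, np.asarray(trait, float))
        rows.append(
            {
                "module": m,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "significant": res.pvalue < 0.05,
            }
        )
    return pd.DataFrame(rows).set_index("module")


def hub_genes(
    ms: ModuleSet,
    modules: list[str] | None = None,
    mm_cut: float = 0.80,
    gs_cut: float = 0.20,
) -> dict[str, list[str]]:
    """Hub genes per module: |MM| > mm_cut and GS > gs_cut (strict)."""
    if ms.gs.empty:
        raise ValueError("gene significance not computed; pass trait to detect_modules")
    modules = modules if modules is not None else ms.modules
    out = {}
    for m in modules:
        members = ms.genes_in(m)
        mm = ms.kme.loc[members, m].abs()
        gs = ms.gs.loc[members]
        out[m] = [g for g in members if mm[g] > mm_cut and gs[g] > gs_cut]
    return out


# ---------------------------------------------------------------------------
# permutation module preservation


def _preservation_stats(
    ref: np.ndarray, test: np.ndarray, beta: int
) -> tuple[float, float]:
    """(mean within-set adjacency in test, cor of intramodular connectivity)."""
    a_t = np.abs(np.corrcoef(test)) ** beta
    np.fill_diagonal(a_t, 0.0)
    n = a_t.shape[0]
    mean_adj = a_t.sum() / (n * (n - 1))
    a_r = np.abs(np.corrcoef(ref)) ** beta
    np.fill_diagonal(a_r, 0.0)
    kim_r, kim_t = a_r.sum(axis=1), a_t.sum(axis=1)
    if np.std(kim_r) == 0 or np.std(kim_t) == 0:
        cor_kim = 0.0
    else:
        cor_kim = float(np.corrcoef(kim_r, kim_t)[0, 1])
    return float(mean_adj), cor_kim


def module_preservation(
    ms: ModuleSet,
    ref_mat: pd.DataFrame,
    test_mat: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Zsummary and medianRank per module between two datasets.

    Observed density (mean within-module adjacency) and connectivity
    (correlation of intramodular connectivity between reference and test)
    statistics are compared against ``n_perm`` size-matched random gene sets
    drawn from the genes shared by both matrices:
    ``Z = (obs − mean_null) / sd_null``; ``Zsummary`` is the mean of the
    density and connectivity Z scores.  ``medianRank`` is the median of the
    modules' ranks under the two observed statistics (1 = best preserved).
    Modules with under half their genes present in the test matrix are
    skipped.
    """
    rng = np.random.default_rng(seed)
    shared = ref_mat.index.intersection(test_mat.index)
    ref = ref_mat.loc[shared]
    test = test_mat.loc[shared]
    rows = []
    for m in ms.modules:
        genes = [g for g in ms.genes_in(m) if g in set(shared)]
        if len(genes) < 0.5 * len(ms.genes_in(m)) or len(genes) < 3:
            warnings.warn(f"module {m}: too few genes in test matrix, skipped")
            continue
        obs_d, obs_c = _preservation_stats(
            ref.loc[genes].to_numpy(), test.loc[genes].to_numpy(), ms.beta
        )
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        pool = np.asarray(shared)
        for p in range(n_perm):
            pick = rng.choice(pool, size=len(genes), replace=False)
            null_d[p], null_c[p] = _preservation_stats(
                ref.loc[pick].to_numpy(), test.loc[pick].to_numpy(), ms.beta
            )
        zd = _z(obs_d, null_d)
        zc = _z(obs_c, null_c)
        rows.append(
            {
                "module": m,
                "n_genes": len(genes),
                "meanAdj": obs_d,
                "corKIM": obs_c,
                "Zdensity": zd,
                "Zconnectivity": zc,
                "Zsummary": np.nanmean([zd, zc]),
                "n_perm": n_perm,
            }
        )
    out = pd.DataFrame(rows).set_index("module")
    if len(out):
        rank_d = out["meanAdj"].rank(ascending=False)
        rank_c = out["corKIM"].rank(ascending=False)
        out["medianRank"] = pd.concat([rank_d, rank_c], axis=1).median(axis=1)
    return out


def _z(obs: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate permutation null (sd = 0)")
        return float("nan")
    return float((obs - null.mean()) / sd)
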