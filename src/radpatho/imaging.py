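"""Bespoke imaging-feature computations.

Three aggregation rules sit at the heart of the multi-modal feature
construction and are implemented here from first principles:

* a minimal handcrafted texture core — fixed-width gray-level binning, the
  gray-level size-zone matrix (GLSZM) and its Small-Area High-Gray-Level
  Emphasis statistic, plus the first-order minimum — covering the two
  handcrafted features that drive grading discrimination;
* the tile-mean rule that turns per-tile handcrafted pathomics vectors into
  one patient-level vector (sampling at most ``max_tiles`` tiles);
* the multiple-instance bag-of-words: patch-level class probabilities are
  histogrammed into a fixed vocabulary over [0, 1] and TF-IDF weighted to
  give one whole-slide feature vector per patient.

Connectivity follows the radiomics convention: 8-connected in 2-D,
26-connected in 3-D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class BinnedImage:
    """Integer gray-level image (levels 1..n_levels) with a mask."""

    values: np.ndarray
    mask: np.ndarray
    n_levels: int


@dataclass
class GLSZM:
    """Size-zone counts ``P[i, j]`` for gray level i+1 and zone size j+1."""

    P: np.ndarray  # (n_levels, max_zone_size) integer counts
    n_zones: int
    n_voxels: int


def bin_image(raw: np.ndarray, mask: np.ndarray, bin_width: float = 25.0) -> BinnedImage:
    """Fixed-bin-width discretisation relative to the in-mask minimum.

    ``level(v) = floor((v - min_in_mask) / bin_width) + 1``.
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raw.shape != mask.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("mask is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = raw[mask].min()
    levels = np.zeros(raw.shape, dtype=int)
    levels[mask] = np.floor((raw[mask] - lo) / bin_width).astype(int) + 1
    return BinnedImage(values=levels, mask=mask, n_levels=int(levels[mask].max()))


def glszm(img: BinnedImage) -> GLSZM:
    """Gray-level size-zone matrix.

    A zone is a maximal connected component of equal gray level inside the
    mask; 8-connectivity in 2-D, 26-connectivity in 3-D.
    """
    structure = np.ones((3,) * img.values.ndim, dtype=int)
    sizes: list[tuple[int, int]] = []
    for level in range(1, img.n_levels + 1):
        binary = (img.values == level) & img.mask
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=structure)
        counts = np.bincount(labeled.ravel())[1:]
        sizes.extend((level, int(c)) for c in counts)
    max_size = max(j for _, j in sizes)
    P = np.zeros((img.n_levels, max_size), dtype=int)
    for i, j in sizes:
        P[i - 1, j - 1] += 1
    return GLSZM(P=P, n_zones=len(sizes), n_voxels=int(img.mask.sum()))


def small_area_high_gray_level_emphasis(m: GLSZM) -> float:
    """SAHGLE = (1/Nz) Σ_{i,j} P(i,j) · i² / j².

    Emphasises small zones of high gray level — jointly fine texture and
    bright intensity.
    """
    if m.n_zones < 1:
        raise ValueError("empty size-zone matrix")
    i = np.arange(1, m.P.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, m.P.shape[1] + 1)[None, :].astype(float)
    return float((m.P * i**2 / j**2).sum() / m.n_zones)


def first_order_minimum(raw: np.ndarray, mask: np.ndarray) -> float:
    """Minimum raw intensity inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return float(np.asarray(raw, dtype=float)[mask].min())


def aggregate_tiles_mean(
    tiles: np.ndarray, max_tiles: int = 50, seed: int | None = None
) -> np.ndarray:
    """Patient-level vector: mean over at most ``max_tiles`` sampled tiles.

    If more tiles are available than ``max_tiles``, a seeded subset is drawn
    without replacement; with fewer, all tiles are used.
    """
    tiles = np.atleast_2d(np.asarray(tiles, dtype=float))
    if tiles.shape[0] == 0:
        raise ValueError("no tiles")
    if tiles.shape[0] > max_tiles:
        rng = np.random.default_rng(seed)
        idx = rng.choice(tiles.shape[0], size=max_tiles, replace=False)
        tiles = tiles[idx]
    return tiles.mean(axis=0)


# ---------------------------------------------------------------------------
# MIL bag-of-words over patch probabilities


@dataclass
class BowVocabulary:
    """Equal-width probability bins on [0, 1] with corpus document frequencies."""

    edges: np.ndarray  # K + 1 edges, 0 to 1
    df: np.ndarray  # documents (bags) containing >= 1 patch per bin
    n_docs: int

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def _bin_counts(probabilities: np.ndarray, edges: np.ndarray) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty patch bag")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("patch probabilities must lie in [0, 1]")
    # right-closed top bin so p == 1.0 falls in the last bin
    idx = np.minimum(np.searchsorted(edges, p, side="right") - 1, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def fit_bow_vocabulary(bags: dict[str, np.ndarray], k: int = 10) -> BowVocabulary:
    """Fit K equal-width bins and per-bin document frequencies on a corpus."""
    if k < 2:
        raise ValueError("need at least 2 bins")
    if not bags:
        raise ValueError("empty corpus")
    edges = np.linspace(0.0, 1.0, k + 1)
    df = np.zeros(k, dtype=int)
    for probs in bags.values():
        df += _bin_counts(probs, edges) > 0
    return BowVocabulary(edges=edges, df=df, n_docs=len(bags))


def bow_tfidf(probabilities: np.ndarray, vocab: BowVocabulary) -> np.ndarray:
    """TF-IDF whole-slide vector for one patch bag.

    tf_k = bin count / bag size; idf_k = ln((1 + N) / (1 + df_k)) + 1
    (smoothed, as in standard text mining); value_k = tf_k · idf_k.
    """
    counts = _bin_counts(probabilities, vocab.edges)
    tf = counts / counts.sum()
    idf = np.log((1.0 + vocab.n_docs) / (1.0 + vocab.df)) + 1.0
    return tf * idf


def bags_to_block(bags: dict[str, np.ndarray], k: int = 10) -> pd.DataFrame:
    """Fit a vocabulary on the corpus and build the DLPF feature block."""
    vocab = fit_bow_vocabulary(bags, k=k)
    rows = {pid: bow_tfidf(probs, vocab) for pid, probs in bags.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"DLPF_bow_{i + 1}" for i in range(vocab.n_bins)]
    df.index.name = "patient_id"
    return df


def read_image_grid(path) -> np.ndarray:
    """Read a tiny plain-text integer/float grid (whitespace separated)."""
    return np.loadtxt(path, dtype=float)
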