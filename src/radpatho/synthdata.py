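"""Synthetic cohort generator with planted, recoverable structure.

Every downstream stage of the pipeline (selection cascade, ensemble,
co-expression network, enrichment, annotation) assumes particular statistical
structure in its inputs.  This module generates seeded cohorts that carry
exactly that structure, together with ground-truth maps, so each stage's
recovery behaviour is assertable:

* four class-conditional Gaussian feature blocks (HRF/DLRF/HPF/DLPF) with
  informative features at a chosen standardized mean difference, redundant
  correlated copies, additive per-site batch offsets and pure-noise filler;
* per-patient bags of patch-level probabilities drawn from grade-specific
  two-component beta mixtures (the bimodal patch-heatmap structure of a
  whole-slide MIL classifier, without any images);
* a latent-factor expression matrix with planted co-expression modules whose
  eigengenes correlate with grade at stated effect sizes.

All randomness flows from a single root seed through ``numpy`` SeedSequence
spawning; generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BLOCKS = ("HRF", "DLRF", "HPF", "DLPF")

#: child-stream indices for SeedSequence spawning, one per generation stage
_STREAMS = {"cohort": 0, "blocks": 1, "bags": 2, "expression": 3}


class SpecificationError(ValueError):
    """Raised when a SyntheticSpec is internally inconsistent."""


@dataclass
class BetaMixture:
    """Two-component beta mixture for patch-level probabilities of one class."""

    a: tuple[float, float]
    b: tuple[float, float]
    weights: tuple[float, float]

    def validate(self) -> None:
        if any(x <= 0 for x in (*self.a, *self.b)):
            raise SpecificationError("beta parameters must be positive")
        if not np.isclose(sum(self.weights), 1.0) or any(w < 0 for w in self.weights):
            raise SpecificationError("mixture weights must be non-negative and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(2, size=n, p=self.weights)
        return rng.beta(np.asarray(self.a)[comp], np.asarray(self.b)[comp])


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate a mid-size multi-institution grading study: a 7:3
    train/hold-out split plus a test set and a small external set, three
    sites, ~40% high-grade prevalence, and per-block signal calibrated so a
    single modality classifies in the 0.7–0.9 AUC band.
    """

    n_patients: dict[str, int] = field(
        default_factory=lambda: {"train": 140, "holdout": 60, "test": 100, "external": 60}
    )
    prevalence: float = 0.4
    n_sites: int = 3
    n_features: dict[str, int] = field(
        default_factory=lambda: {b: 60 for b in BLOCKS}
    )
    n_informative: dict[str, int] = field(
        default_factory=lambda: {b: 5 for b in BLOCKS}
    )
    effect_size: float = 0.8
    redundancy_rho: float = 0.9
    site_shift_sd: float = 0.3
    bag_size_range: tuple[int, int] = (30, 80)
    # both classes share a low-probability and a high-probability patch
    # component; grades differ in composition, so bag-level separation is
    # driven by the high-probability patch fraction with binomial overlap
    bag_mixture: dict[int, BetaMixture] = field(
        default_factory=lambda: {
            0: BetaMixture(a=(2.0, 8.0), b=(8.0, 2.0), weights=(0.85, 0.15)),
            1: BetaMixture(a=(2.0, 8.0), b=(8.0, 2.0), weights=(0.75, 0.25)),
        }
    )
    n_genes: int = 600
    module_sizes: tuple[int, ...] = (100, 80)
    module_grade_r: tuple[float, ...] = (0.42, 0.34)
    loading_range: tuple[float, float] = (0.55, 0.95)
    hub_loading: float = 0.85
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.n_patients or any(n <= 0 for n in self.n_patients.values()):
            raise SpecificationError("split sizes must be positive")
        if not 0 < self.prevalence < 1:
            raise SpecificationError("prevalence must be in (0, 1)")
        if self.n_sites < 1:
            raise SpecificationError("need at least one site")
        for b in self.n_features:
            if self.n_features[b] <= 0:
                raise SpecificationError(f"n_features[{b}] must be positive")
            if self.n_informative.get(b, 0) < 0:
                raise SpecificationError("n_informative must be non-negative")
            # informative + one redundant copy each must fit in the block
            if 2 * self.n_informative.get(b, 0) > self.n_features[b]:
                raise SpecificationError(f"block {b}: too many informative features")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise SpecificationError("invalid bag_size_range")
        for mix in self.bag_mixture.values():
            mix.validate()
        if sum(self.module_sizes) > self.n_genes:
            raise SpecificationError("module sizes exceed n_genes")
        if len(self.module_sizes) != len(self.module_grade_r):
            raise SpecificationError("one grade correlation per module required")
        if any(abs(r) >= 1 for r in self.module_grade_r):
            raise SpecificationError("|module_grade_r| must be < 1")
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named stage, independent across stages."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Patient table with grade label, site and dataset split.

    Grade counts per split are fixed at ``round(n * prevalence)`` (both
    classes always present); sites are assigned round-robin so every site is
    non-empty, then shuffled within split.
    """
    spec.validate()
    rng = spec.rng("cohort")
    rows = []
    for split, n in spec.n_patients.items():
        n_high = int(round(n * spec.prevalence))
        n_high = min(max(n_high, 1), n - 1)  # both classes in every split
        grade = np.zeros(n, dtype=int)
        grade[:n_high] = 1
        rng.shuffle(grade)
        site = np.arange(n) % spec.n_sites
        rng.shuffle(site)
        for i in range(n):
            rows.append((f"{split}_{i:04d}", grade[i], f"site{site[i]}", split))
    return pd.DataFrame(rows, columns=["patient_id", "grade", "site", "split"])


def _block_features(
    cohort: pd.DataFrame,
    block: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    n = len(cohort)
    p = spec.n_features[block]
    k = spec.n_informative[block]
    grade = cohort["grade"].to_numpy(float)
    X = rng.standard_normal((n, p))
    # class-conditional mean shift on informative columns (unit residual SD,
    # so effect_size is the standardized mean difference)
    X[:, :k] += spec.effect_size * grade[:, None]
    # one redundant copy per informative feature at correlation redundancy_rho
    rho = spec.redundancy_rho
    for j in range(k):
        resid = rng.standard_normal(n)
        X[:, k + j] = rho * X[:, j] + np.sqrt(1 - rho**2) * resid
    # additive per-(site, feature) offsets
    if spec.site_shift_sd > 0:
        sites = sorted(cohort["site"].unique())
        offsets = rng.normal(0.0, spec.site_shift_sd, size=(len(sites), p))
        site_idx = cohort["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
        X = X + offsets[site_idx]
    names = [f"{block}_{j + 1}" for j in range(p)]
    truth = {
        "informative": names[:k],
        "redundant": {names[k + j]: names[j] for j in range(k)},
        "signal_groups": [[names[j], names[k + j]] for j in range(k)],
    }
    df = pd.DataFrame(X, index=cohort["patient_id"].to_numpy(), columns=names)
    df.index.name = "patient_id"
    return df, truth


def generate_feature_blocks(
    cohort: pd.DataFrame, spec: SyntheticSpec
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Four patient × feature blocks plus the planted-signal ground truth.

    Each redundant copy is an attenuated noisy replicate of its parent, so it
    carries the same class signal scaled by ``redundancy_rho``; the
    ``signal_groups`` entry of the truth map groups each parent with its copy
    for recovery scoring (selecting either member recovers the signal).
    """
    spec.validate()
    if cohort.groupby("grade").size().min() < 2:
        raise SpecificationError("need at least 2 patients per class")
    rng = spec.rng("blocks")
    blocks, truth = {}, {}
    for b in BLOCKS:
        blocks[b], truth[b] = _block_features(cohort, b, spec, rng)
    return blocks, truth


def generate_patch_bags(
    cohort: pd.DataFrame, spec: SyntheticSpec
) -> dict[str, np.ndarray]:
    """Per-patient vectors of patch-level high-grade probabilities.

    Bag sizes are uniform over ``bag_size_range``; probabilities follow the
    grade-specific beta mixture of the patient's class.
    """
    spec.validate()
    rng = spec.rng("bags")
    lo, hi = spec.bag_size_range
    bags = {}
    for pid, grade in zip(cohort["patient_id"], cohort["grade"]):
        size = int(rng.integers(lo, hi + 1))
        bags[pid] = spec.bag_mixture[int(grade)].sample(size, rng)
    return bags


def generate_expression(
    cohort: pd.DataFrame,
    spec: SyntheticSpec,
    fpkm: bool = False,
    noise_seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Latent-factor expression matrix (genes × samples) with planted modules.

    Module eigengene m is ``r_m * z(grade) + sqrt(1 - r_m^2) * eps`` so its
    population correlation with grade is ``r_m``.  Each module gene is
    ``loading * eigengene + noise_sd * eps`` with loadings uniform over
    ``loading_range``; genes with loading >= ``hub_loading`` are flagged as
    planted hubs in the truth map.  Background genes are independent noise.

    Loadings (the biological module structure) are drawn from a stream fixed
    by the spec seed, while residuals come from a separate noise stream that
    can be re-seeded via ``noise_seed``: two cohorts generated from the same
    spec but different ``noise_seed`` share their module structure, the
    situation a cross-dataset preservation analysis assumes.

    Values are on a log2-TPM-like scale.  With ``fpkm=True`` the matrix is
    passed through ``2**x`` and rescaled per sample to mimic FPKM abundances,
    solely to exercise the FPKM→TPM converter.
    """
    spec.validate()
    rng = spec.rng("expression")
    nrng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if noise_seed is None else noise_seed, 97])
    )
    n = len(cohort)
    grade = cohort["grade"].to_numpy(float)
    zg = (grade - grade.mean()) / grade.std()
    X = np.empty((spec.n_genes, n))
    genes = [f"gene{g + 1:04d}" for g in range(spec.n_genes)]
    assign = {}
    hubs = []
    eigengenes = {}
    start = 0
    for m, (size, r) in enumerate(zip(spec.module_sizes, spec.module_grade_r)):
        name = f"M{m + 1}"
        ev = r * zg + np.sqrt(1 - r**2) * nrng.standard_normal(n)
        eigengenes[name] = ev
        loadings = rng.uniform(*spec.loading_range, size=size)
        noise = nrng.standard_normal((size, n)) * spec.noise_sd
        X[start : start + size] = loadings[:, None] * ev[None, :] + noise
        for j in range(size):
            g = genes[start + j]
            assign[g] = name
            if loadings[j] >= spec.hub_loading:
                hubs.append(g)
        start += size
    X[start:] = nrng.standard_normal((spec.n_genes - start, n))
    X += 6.0  # shift to a plausible log2(TPM+1) location
    mat = pd.DataFrame(X, index=genes, columns=cohort["patient_id"].to_numpy())
    mat.index.name = "gene"
    if fpkm:
        lin = np.maximum(2.0**mat - 1.0, 0.0)
        mat = lin / lin.sum(axis=0) * 1e6 * np.exp(rng.normal(0, 0.1, size=n))
    truth = {
        "modules": assign,
        "hub_genes": hubs,
        "module_grade_r": dict(zip(eigengenes, spec.module_grade_r)),
        "eigengenes": {k: v.tolist() for k, v in eigengenes.items()},
    }
    return mat, truth


# ---------------------------------------------------------------------------
# plain-text writers


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def write_feature_block(block: pd.DataFrame, path: str | Path) -> None:
    block.to_csv(path)


def write_patch_bags(bags: dict[str, np.ndarray], path: str | Path) -> None:
    """Long CSV: patient_id, patch_id, probability."""
    rows = [
        (pid, i, p)
        for pid, probs in bags.items()
        for i, p in enumerate(probs)
    ]
    pd.DataFrame(rows, columns=["patient_id", "patch_id", "probability"]).to_csv(
        path, index=False
    )


def read_patch_bags(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        pid: g["probability"].to_numpy()
        for pid, g in df.groupby("patient_id", sort=False)
    }


def write_expression(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t")


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
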