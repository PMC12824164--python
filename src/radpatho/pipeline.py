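"""End-to-end orchestration of the radiopathomics grading analysis.

Stage order: synthetic cohort → feature construction (including the MIL
bag-of-words DLPF block) → per-block selection cascade and SNR screen →
per-modality champions and the weighted-voting DHRPs ensemble → evaluation →
co-expression network, preservation and hub genes → pathway enrichment and
per-sample scores → feature–pathway annotation with post-hoc power.

Every printed analysis threshold is a named field of :class:`RunConfig`, so
the config doubles as a parameter ledger.  ``run`` writes one artifact
directory with per-stage CSV/JSON outputs and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from radpatho import enrichment, evaluation, imaging, network, power, selection, synthdata
from radpatho.ensemble import ensemble_cv_auc, fit_dhrps, fit_modality_model
from radpatho.synthdata import BLOCKS, SyntheticSpec

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults mirror the study's printed settings."""

    seed: int = 0
    # selection cascade
    anova_alpha: float = 0.05
    prune_threshold: float = 0.8
    boruta_max_iter: int = 50
    boruta_trees: int = 100
    lasso_folds: int = 10
    snr_cut: float = 2.0
    # ensemble
    cv_folds: int = 5
    # network
    rsquared_cut: float = 0.85
    min_module_size: int = 30
    merge_cut_height: float = 0.35
    zsummary_cut: float = 10.0
    preservation_perms: int = 100
    mm_cut: float = 0.80
    gs_cut: float = 0.20
    # enrichment / annotation
    ora_fdr: float = 0.05
    pathway_fdr: float = 0.05
    gsea_perms: int = 500
    annotation_fdr: float = 0.1
    annotation_top_k: int = 5
    power_alpha: float = 0.05
    power_target: float = 0.8
    bow_bins: int = 10
    # stage toggles
    stages: tuple[str, ...] = ("synth", "features", "select", "model", "eval", "network", "enrich", "annotate")
    synth: SyntheticSpec = field(default_factory=SyntheticSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth:
            cfg.synth = SyntheticSpec(**synth)
        if "seed" in raw:
            cfg.synth.seed = cfg.seed
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(results: dict, key: str, stage: str) -> object:
    if key not in results:
        raise RuntimeError(
            f"stage {stage!r} needs the {key!r} artifact; enable its upstream stage"
        )
    return results[key]


def synthetic_gene_sets(
    truth: dict, universe: list[str], seed: int, n_random: int = 8, frac: float = 0.6
) -> dict[str, list[str]]:
    """Gene sets for enrichment tests on a synthetic cohort.

    One set per planted module (a seeded ``frac`` subsample of its genes
    topped up with random background) plus ``n_random`` size-matched random
    sets, so over-representation is assertable in both directions.
    """
    rng = np.random.default_rng(seed)
    modules: dict[str, list[str]] = {}
    for g, m in truth["modules"].items():
        modules.setdefault(m, []).append(g)
    sets = {}
    for m, genes in modules.items():
        take = rng.choice(genes, size=max(3, int(frac * len(genes))), replace=False)
        pad = rng.choice(
            [g for g in universe if g not in set(genes)],
            size=max(2, len(take) // 5),
            replace=False,
        )
        sets[f"PATHWAY_{m}"] = sorted(set(take) | set(pad))
    for i in range(n_random):
        sets[f"PATHWAY_RANDOM_{i + 1}"] = sorted(
            rng.choice(universe, size=min(40, len(universe)), replace=False)
        )
    return sets


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}
    spec = config.synth
    stages = set(config.stages)

    def timed(name):
        t0 = time.time()

        def done():
            manifest["stages"][name] = round(time.time() - t0, 2)
            log.info("stage %s done in %.1fs", name, time.time() - t0)

        return done

    if "synth" in stages:
        fin = timed("synth")
        cohort = synthdata.generate_cohort(spec)
        blocks, block_truth = synthdata.generate_feature_blocks(cohort, spec)
        bags = synthdata.generate_patch_bags(cohort, spec)
        expr_train, expr_truth = synthdata.generate_expression(
            cohort[cohort["split"] == "train"].reset_index(drop=True), spec
        )
        expr_ext, _ = synthdata.generate_expression(
            cohort[cohort["split"] == "external"].reset_index(drop=True),
            spec,
            noise_seed=spec.seed + 1,
        )
        results.update(
            cohort=cohort, blocks=blocks, block_truth=block_truth, bags=bags,
            expr_train=expr_train, expr_truth=expr_truth, expr_ext=expr_ext,
        )
        synthdata.write_cohort(cohort, out / "cohort.csv")
        synthdata.write_expression(expr_train, out / "expression_train.tsv")
        synthdata.write_truth(
            {k: v for k, v in expr_truth.items() if k != "eigengenes"},
            out / "expression_truth.json",
        )
        fin()

    if "features" in stages:
        fin = timed("features")
        bags = _require(results, "bags", "features")
        blocks = dict(_require(results, "blocks", "features"))
        # replace the Gaussian DLPF placeholder with the MIL bag-of-words block
        cohort = results["cohort"]
        train_ids = cohort.loc[cohort["split"] == "train", "patient_id"]
        vocab = imaging.fit_bow_vocabulary(
            {pid: bags[pid] for pid in train_ids}, k=config.bow_bins
        )
        dlpf = pd.DataFrame(
            {pid: imaging.bow_tfidf(bags[pid], vocab) for pid in cohort["patient_id"]}
        ).T
        dlpf.columns = [f"DLPF_bow_{i + 1}" for i in range(vocab.n_bins)]
        dlpf.index.name = "patient_id"
        blocks["DLPF"] = dlpf
        results["blocks"] = blocks
        for name, b in blocks.items():
            b.to_csv(out / f"block_{name}.csv")
        fin()

    if "select" in stages:
        fin = timed("select")
        cohort = _require(results, "cohort", "select")
        blocks = _require(results, "blocks", "select")
        train_mask = cohort["split"] == "train"
        train_ids = cohort.loc[train_mask, "patient_id"]
        y_train = cohort.loc[train_mask, "grade"].to_numpy()
        selected: dict[str, list[str]] = {}
        scaled_blocks: dict[str, pd.DataFrame] = {}
        reports = {}
        for name in BLOCKS:
            block = blocks[name]
            scaled, _ = selection.zscore(block, train_index=train_ids)
            scaled_blocks[name] = scaled
            rep = selection.run_cascade(
                scaled.loc[train_ids],
                y_train,
                alpha=config.anova_alpha,
                prune_threshold=config.prune_threshold,
                boruta_max_iter=config.boruta_max_iter,
                boruta_trees=config.boruta_trees,
                lasso_folds=config.lasso_folds,
                seed=config.seed,
            )
            selected[name] = rep.selected
            reports[name] = rep
        results.update(selected=selected, scaled_blocks=scaled_blocks, selection_reports=reports)
        # post-hoc SNR stability screen on the final feature set
        final_cols = [c for name in BLOCKS for c in selected[name]]
        if final_cols:
            concat = pd.concat(
                [scaled_blocks[n][selected[n]] for n in BLOCKS if selected[n]], axis=1
            )
            snr_rep = selection.snr(
                concat.loc[train_ids], cohort.loc[train_mask, "site"].to_numpy()
            )
            results["snr"] = snr_rep
            snr_rep.to_csv(out / "snr.csv")
        (out / "selection.json").write_text(
            json.dumps({n: selected[n] for n in BLOCKS}, indent=1)
        )
        fin()

    if "model" in stages:
        fin = timed("model")
        cohort = _require(results, "cohort", "model")
        selected = _require(results, "selected", "model")
        scaled_blocks = results["scaled_blocks"]
        train_mask = cohort["split"] == "train"
        train_ids = cohort.loc[train_mask, "patient_id"]
        y_train = cohort.loc[train_mask, "grade"].to_numpy()
        champions = {}
        for name in BLOCKS:
            if not selected[name]:
                log.warning("block %s: empty selection, skipping champion", name)
                continue
            champions[name] = fit_modality_model(
                scaled_blocks[name].loc[train_ids, selected[name]],
                y_train,
                n_folds=config.cv_folds,
                seed=config.seed,
            )
        concat = pd.concat(
            [scaled_blocks[n][selected[n]] for n in BLOCKS if selected[n]], axis=1
        )
        dhrps = fit_dhrps(
            concat.loc[train_ids], y_train, n_folds=config.cv_folds, seed=config.seed
        )
        dhrps_cv = ensemble_cv_auc(
            concat.loc[train_ids], y_train, n_folds=config.cv_folds, seed=config.seed
        )
        results.update(champions=champions, dhrps=dhrps, features_concat=concat, dhrps_cv_auc=dhrps_cv)
        (out / "model_manifest.json").write_text(
            json.dumps(
                {
                    "champions": {n: {"learner": c.name, "cv_auc": c.cv_auc} for n, c in champions.items()},
                    "dhrps_cv_auc": dhrps_cv,
                    **dhrps.manifest(),
                },
                indent=1,
            )
        )
        fin()

    if "eval" in stages:
        fin = timed("eval")
        cohort = _require(results, "cohort", "eval")
        dhrps = _require(results, "dhrps", "eval")
        concat = results["features_concat"]
        train_mask = cohort["split"] == "train"
        train_ids = cohort.loc[train_mask, "patient_id"]
        y_train = cohort.loc[train_mask, "grade"].to_numpy()
        thr = evaluation.youden_threshold(dhrps.predict(concat.loc[train_ids]), y_train)
        reports = {}
        for split in cohort["split"].unique():
            ids = cohort.loc[cohort["split"] == split, "patient_id"]
            y = cohort.loc[cohort["split"] == split, "grade"].to_numpy()
            s = dhrps.predict(concat.loc[ids])
            auc, var, ci = evaluation.auc_delong(s, y)
            reports[split] = {
                "auc": auc,
                "auc_ci": list(ci),
                **evaluation.threshold_metrics(s, y, thr),
            }
        results["eval"] = reports
        (out / "evaluation.json").write_text(json.dumps(reports, indent=1))
        fin()

    if "network" in stages:
        fin = timed("network")
        if "expr_train" not in results:
            raise RuntimeError("stage 'network' needs expression data; enable 'synth'")
        cohort = results["cohort"]
        expr = results["expr_train"]
        train = cohort[cohort["split"] == "train"]
        params = network.NetworkParams(
            rsquared_cut=config.rsquared_cut,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
        )
        pre = network.preprocess(expr, log_transform=False)
        beta, fit_table = network.pick_soft_threshold(pre, params)
        trait = train["grade"].to_numpy()
        ms = network.detect_modules(pre, beta, params, trait=trait)
        mt = network.module_trait(ms, trait)
        pre_ext = network.preprocess(results["expr_ext"], log_transform=False)
        pres = network.module_preservation(
            ms, pre, pre_ext, n_perm=config.preservation_perms, seed=config.seed
        )
        reproducible = pres.index[pres["Zsummary"] >= config.zsummary_cut].tolist()
        significant = mt.index[(mt["significant"]) & (mt.index.isin(reproducible))].tolist()
        hubs = network.hub_genes(ms, significant, config.mm_cut, config.gs_cut)
        results.update(
            modules=ms, module_trait=mt, preservation=pres,
            grade_modules=significant, hubs=hubs, expr_pre=pre, beta=beta,
        )
        hub_set = {g for v in hubs.values() for g in v}
        pd.DataFrame(
            {
                "module": ms.labels,
                "kme_own": [
                    ms.kme.loc[g, m] if m != network.GREY else np.nan
                    for g, m in ms.labels.items()
                ],
                "gs": ms.gs,
                "hub": ms.labels.index.map(lambda g: g in hub_set),
            }
        ).to_csv(out / "modules.csv")
        mt.to_csv(out / "module_trait.csv")
        pres.to_csv(out / "preservation.csv")
        fin()

    if "enrich" in stages:
        fin = timed("enrich")
        ms = _require(results, "modules", "enrich")
        pre = results["expr_pre"]
        cohort = results["cohort"]
        train = cohort[cohort["split"] == "train"]
        universe = pre.index.tolist()
        sets = synthetic_gene_sets(results["expr_truth"], universe, config.seed)
        enrichment.write_gmt(sets, out / "gene_sets.gmt")
        ora_tables = {
            m: enrichment.ora(ms.genes_in(m), sets, universe, config.ora_fdr)
            for m in results.get("grade_modules", ms.modules)
        }
        enriched = sorted(
            {s for t in ora_tables.values() for s in t.index[t["significant"]]}
        )
        scores = enrichment.ssgsea_score(pre, {s: sets[s] for s in enriched} or sets)
        comparison = enrichment.compare_pathways(
            scores, train["grade"].to_numpy(), config.pathway_fdr
        )
        gsea_res = enrichment.gsea(
            pre, train["grade"].to_numpy(), sets,
            n_perm=config.gsea_perms, seed=config.seed,
        )
        results.update(
            gene_sets=sets, ora=ora_tables, enriched_pathways=enriched,
            pathway_scores=scores, pathway_comparison=comparison, gsea=gsea_res,
        )
        scores.to_csv(out / "pathway_scores.csv")
        comparison.to_csv(out / "pathway_comparison.csv")
        gsea_res.to_csv(out / "gsea.csv")
        fin()

    if "annotate" in stages:
        fin = timed("annotate")
        scores = _require(results, "pathway_scores", "annotate")
        cohort = results["cohort"]
        concat = _require(results, "features_concat", "annotate")
        train_ids = cohort.loc[cohort["split"] == "train", "patient_id"]
        annotation = power.annotate_features(
            concat.loc[train_ids],
            scores.loc[train_ids],
            fdr_cut=config.annotation_fdr,
            top_k=config.annotation_top_k,
        )
        preport = power.power_report(
            annotation, n=len(train_ids), alpha=config.power_alpha,
            target_power=config.power_target,
        )
        results.update(annotation=annotation, power_report=preport)
        annotation.to_csv(out / "annotation.csv", index=False)
        preport.to_csv(out / "power_report.csv", index=False)
        fin()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
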