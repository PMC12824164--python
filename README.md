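# radpatho

Grading invasive pulmonary adenocarcinoma (IPA) from multi-modal imaging
features, with a transcriptomic interpretation layer.

IPA is graded by the IASLC system into grades I–III; the clinically decisive
distinction is **high-grade (III) vs non-high-grade**. This package
implements a reusable version of a radiopathomics grading analysis for that
task, for researchers who have (or want to simulate) four patient-level
feature blocks — handcrafted radiomics (HRF), deep-learning radiomics
(DLRF), handcrafted pathomics (HPF) and deep-learning pathomics (DLPF) —
plus bulk RNA expression:

1. **Feature construction** — a minimal handcrafted texture core (fixed-width
   binning, GLSZM, Small-Area High-Gray-Level Emphasis, first-order
   minimum), tile-mean pathomics aggregation, and a multiple-instance
   bag-of-words: patch-level class probabilities binned over [0, 1] and
   TF-IDF weighted into one whole-slide vector per patient.
2. **Feature selection** — per modality: z-score → ANOVA (α = 0.05) →
   Spearman redundancy prune (|ρ| ≥ 0.8) → Boruta shadow-feature screen →
   L1-logistic selection, plus an inter-site stability screen
   SNR = √(σ²_within/σ²_site) with SNR ≥ 2 flagged reliable.
3. **Grading ensemble (DHRPs)** — eleven probabilistic learners combined by
   weighted voting, w_m ∝ max(AUC_m − ½, 0), s(x) = Σ w_m p_m(x).
4. **Evaluation** — DeLong AUC CIs and paired tests, Youden-point confusion
   metrics, calibration, decision-curve net benefit, operating-point-matched
   rater comparison with exact McNemar, Cohen's κ, ICC(2,1).
5. **Co-expression interpretation** — WGCNA-style modules (soft threshold at
   scale-free R² ≥ 0.85, TOM clustering, minModuleSize 30, mergeCutHeight
   0.35), permutation preservation (Zsummary ≥ 10), module–trait Spearman
   correlation, hub genes (|MM| > 0.80, GS > 0.20), hypergeometric ORA
   (FDR < 0.05), per-sample pathway scores, Mann–Whitney group comparison,
   GSEA, and feature–pathway annotation (Pearson, FDR < 0.1, top 5 per
   feature) with post-hoc correlation power and the minimum detectable
   correlation coefficient (MDCC).

A seeded synthetic-cohort generator (`radpatho.synthdata`) plants all of the
structure the pipeline assumes — class-conditional feature blocks with site
batch effects, grade-dependent beta-mixture patch bags, and a latent-factor
expression model with grade-correlated modules — together with ground-truth
maps, so every stage's recovery behaviour is testable without any private
clinical data. See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

```python
from radpatho import power
from radpatho.pipeline import RunConfig, run

# post-hoc power of a module-grade correlation observed at n = 36
print(round(power.correlation_power(0.42, 36, alpha=0.05), 3))  # 0.740
print(round(power.correlation_power(0.34, 36, alpha=0.05), 3))  # 0.539
print(round(power.mdcc(36, alpha=0.05, target_power=0.8), 3))   # 0.448

# end-to-end synthetic analysis
cfg = RunConfig(seed=1)
cfg.synth.seed = 1
res = run(cfg, "runs/demo")
print({b: round(c.cv_auc, 3) for b, c in res["champions"].items()})
# {'HRF': 0.883, 'DLRF': 0.87, 'HPF': 0.906, 'DLPF': 0.9}
print(round(res["dhrps_cv_auc"], 3))                            # 0.972
print(res["preservation"]["Zsummary"].round(1).to_dict())
# {'blue': 32.0, 'turquoise': 17.7}
```

The first three numbers are the achieved power of the two-sided Pearson
test at the observed module–grade correlations and the smallest correlation
detectable at 80% power for that sample size. The champion AUCs show each
modality classifying in the 0.85–0.90 band on the synthetic training
cohort, and the weighted-voting ensemble improving on the best single
modality. The preservation Zsummary values exceed the ≥ 10 reproducibility
rule for both planted modules (exact values vary with the run's seed).

The same pipeline runs from a shell:

```bash
radpatho run --out runs/demo --seed 1
radpatho synth --out data/synthetic --seed 7
radpatho power --r 0.42 --n 36
```

Real-data mode consumes CSV/TSV tables with the same layout as the
generator's writers (cohort CSV, per-block feature CSVs, patch-bag long
CSV, expression TSV, GMT gene sets).

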