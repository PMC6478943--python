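# pmlsubtypes

Molecular subtyping of bronchial premalignant lesions (PMLs) from bulk
RNA-seq — as a tested, reproducible pipeline.

Bronchial PMLs are precursors of lung squamous cell carcinoma with highly
variable outcomes; histology alone does not tell which lesions will
progress. This package implements a transcriptomic subtyping workflow for
endobronchial biopsies and matched airway brushes, exercised end to end on
synthetic multi-dataset expression data with planted ground truth:

1. **Preprocessing** — TMM library normalization with log2-CPM, gene
   filtering (zero IQR or row sum ≤ 1), multi-criterion sample QC
   (mean inter-sample correlation, expression PC1/PC2, transcript integrity
   number; excluded only when more than one criterion is > 2 SD from the
   mean), a Y-gene sex check, and per-gene residualization on RNA quality
   and batch.
2. **Co-expression modules** — weighted unsigned networks
   (a_ij = |cor(x_i, x_j)|^β), topological overlap
   TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
   average-linkage tree cutting, eigengene (PC1) summaries.
3. **Cross-dataset conservation** — module PC1s computed in every dataset,
   absolute Pearson correlations binarized at r > 0.85, summed across
   datasets; biopsy modules with a partner conserved in *all* datasets are
   retained, and their genes intersected with the partners'.
4. **Consensus subtyping** — PAM (k-medoids) on 1 − Pearson distance over
   1000 subsampling iterations (80% of samples), k selected from the
   relative change Δ(k) of the area under the consensus CDF, final
   assignments by hierarchical clustering of the consensus matrix, and
   subtypes named from the up/down pattern of module scores
   (Proliferative, Inflammatory, Secretory, Normal-like).
5. **Classification** — a 22-gene nearest-centroid subtype predictor with
   inverse-proportional gene allocation across modules, joint
   ComBat + z-score normalization of train and test cohorts, and an 8-gene
   sub-panel that detects the Proliferative subtype in normal-appearing
   brushes (evaluated against matched biopsies from the same procedure).
6. **Association** — GSVA-style single-sample module scores (Gaussian
   kernel CDF, weighted Kolmogorov–Smirnov random walk), repeated-measures
   association with an exchangeable within-subject correlation
   (duplicateCorrelation-style consensus ρ + GLS), BH-FDR, rank-based AUC,
   exact Fisher tests, and local Fisher gene-set enrichment.

The synthetic-data generator (`pmlsubtypes.simulate`) is first-class code:
an additive latent-factor model that plants shared and dataset-private
modules across four linked datasets (biopsy / brush / tumor-like /
mouse-like; 190/89/471/25 samples), four biopsy subtypes driven by module
direction patterns, subject effects with repeated biopsies, batch and TIN
covariates, and a progression label anti-correlated with module M9 —
so every stage of the pipeline can be validated against known truth.

## Worked example

```python
from pmlsubtypes import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(sim=SimulationConfig(seed=1), seed=1, consensus_iters=250)
result = run_pipeline(cfg)
print(result.report["chosen_k"], result.report["subtype_sizes"])
```

prints

```
4 {'Secretory': 62, 'Proliferative': 46, 'Inflammatory': 41, 'Normal-like': 40}
```

meaning the consensus CDF evidence selected four subtypes, and the
discovered clusters were named by matching their module up/down signature
to the expected subtype patterns. On this run the report further shows
9 retained modules (360 genes), 98.9% training accuracy for the 22-gene
classifier, brush presence calls with 95% specificity / 47% sensitivity,
and module M9 as the top progression association (q ≈ 7e-5, AUC 0.84) —
the planted high-specificity / low-sensitivity brush regime and the planted
immune-module progression signal, recovered.

The `examples/` directory walks through each capability separately
(simulation, module conservation, subtype discovery, classification,
progression association); each script prints the numbers it computes with a
line on what they mean.

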