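# tmekit

Tools for two questions that come up when comparing tumor microenvironments
(TMEs) across mouse colorectal-tumor models:

1. **Which cell types are talking to the tumor?** Given a single-cell
   RNA-seq count matrix with cell-type and replicate annotations and a
   prior-knowledge table of ligand→receptor interactions, `tmekit` scores
   candidate communication from a sender cell type (e.g. a
   cancer-associated fibroblast, CAF) to a receiver cell type (e.g. tumor
   or squamous epithelial cells).
2. **How abundant are CAF subtypes inside tumor regions?** Given a
   multiplexed immunofluorescence (MxIF) image, `tmekit` thresholds marker
   channels into binary masks, overlays the two markers that define each
   CAF subtype (CAF1 = VIM ∧ SMA, CAF2 = PDGFRα ∧ TNC), and normalizes the
   CAF-positive area inside the β-catenin tumor mask to the tumor area.

A synthetic-data module generates count matrices, interaction priors, and
multichannel images with planted ground truth, so the whole pipeline is
testable without any download.

## The model

**Normalization.** Counts are scaled per cell to 10,000 and log-transformed:
`x_gc = log2(count_gc / total_c × 10⁴ + 1)`.

**Differential expression.** For each gene and each (cell type, sample)
stratum, the cells of that type in that sample (foreground) are compared
against the pooled cells of all other cell types (background) with a
two-part *hurdle* test suited to zero-inflated single-cell data: a
binomial likelihood-ratio test on detection (x > 0) plus a Gaussian
likelihood-ratio test on the positive values, summed and referred to a
χ² with as many degrees of freedom as components fitted (2, or 1 when a
component is degenerate). P-values across all genes and strata are
adjusted with Benjamini–Hochberg.

**RL score.** For a prior edge (L, R), a sender S and receiver T, in
sample s:

    RL-score(L, R, s) = log2(FC_L × FC_R) = log2FC(L | S, s) + log2FC(R | T, s)

where `log2FC = log2(mean linear expression + 1) − log2(background mean + 1)`.
An edge is flagged **significant** for a condition group only when in
*every* replicate sample of that group: both adjusted p-values < 0.01,
ligand log2FC ≥ 0.5, and receptor log2FC > 0.

**MxIF abundance.** `normalized_abundance = |CAF mask ∧ tumor mask| / |tumor mask|`,
with group differences tested by a pooled-variance Student's t-test.

## Worked example

Run the standard synthetic recovery study (four cell types, three replicate
samples, three true ligand→receptor edges planted at log2FC = 2 on both
partners among 20 decoy edges):

```python
from tmekit.study import run_simulation_study

report = run_simulation_study(seed=7, cells_per_type_per_sample=500)
for k, v in report.items():
    if k != "tables":
        print(f"{k}: {v}")
```

```
rl_precision: 1.0
rl_recall: 1.0
n_significant_edges: 3
lfc_recovery_max_abs_error: 0.11403556553358563
hurdle_null_rejection_rate: 0.053
mxif_max_abs_error: 0.0
```

All three planted edges — and no decoys — pass the consistency filter
(precision and recall 1.0); the worst per-stratum error on the planted
log2 fold change of 2 is 0.11; the hurdle test rejects at 5.3% under the
null at α = 0.05; and the image quantification recovers the planted
abundances exactly at this noise level. The flagged edges themselves:

```
ligand receptor  rl_score
 g0000    g0003  3.919649
 g0001    g0004  3.956960
 g0002    g0005  4.002285
```

Each score ≈ 4 = log2(4 × 4): both partners were planted at linear
fold change 4.

The same stages are exposed as subcommands of the `tmekit` CLI
(`simulate`, `qc`, `normalize`, `de`, `rl-score`, `mxif-quant`, `study`);
see `tmekit --help`.

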