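# Methods

## Scope and data model

`tmekit` operates on three inputs: a gene × cell integer count matrix with
a per-cell annotation (cell type, replicate sample, condition group), a
directed ligand→receptor prior-knowledge table with mode-of-action labels,
and a multichannel immunofluorescence image with a channel→marker map.
Counts live in an `AnnData` (cells × genes) with the annotation in `obs`;
on disk they are MatrixMarket MTX (gene × cell) plus `genes.tsv`,
`barcodes.tsv`, and `annotation.tsv`. Images are multichannel TIFF with a
YAML channel map.

## Quality control

A cell is removed when it has strictly fewer than 500 genes detected or
strictly more than 15% of its counts on genes whose names carry the
mitochondrial prefix (`mt-`, mouse nomenclature). Both inequalities are
strict — a 500-gene cell and a cell at exactly 15% mitochondrial counts
are retained — and the filter is idempotent. The thresholds assume
whole-transcriptome data; simulation studies that use a reduced gene
universe scale `min_genes_detected` down accordingly (the packaged study
harness uses 10 against its 300-gene universe).

## Normalization

Per cell: divide by the cell's total counts, multiply by 10,000, and take
log2(x + 1). Zero counts map to exactly 0, and a cell with zero total
counts (possible after subsetting) maps to all zeros rather than erroring.
The transform is exactly invertible per cell: summing 2^x − 1 over genes
returns 10,000 for every nonzero cell, which the tests assert to 1e-6
relative tolerance. Base 2 is used throughout so that downstream fold
changes and RL scores live on one consistent scale.

## Hurdle differential expression

For each gene and each (cell type, sample) stratum, foreground = the cells
of that type in that sample. The default background is the pooled cells of
**all other cell types across all samples**. Two alternatives are provided
(`background="complement"`: every cell not in the foreground, including
the same type in other samples; `"within_group"`: other types restricted
to the stratum's own group). The default excludes the foreground's cell
type everywhere because a type-specific effect present in every replicate
would otherwise contaminate the background and attenuate its own fold
change — with three replicate samples, a planted log2FC of 2 would
measure ≈ 1.5 under the complement background.

The test is the standard two-part hurdle construction for zero-inflated
expression, with the group indicator as the only covariate (no
detection-rate or other latent covariates):

* **discrete part** — binomial likelihood-ratio (G-)test of detection
  (x > 0) between the two groups;
* **continuous part** — Gaussian likelihood-ratio test on the positive
  values only (log2 scale), equal-variance MLE fits with and without the
  group mean term, LR = n·ln(RSS₀/RSS₁).

The two LR statistics are summed and referred to χ² with df = the number
of components actually fitted. Degenerate cases: a gene undetected in
both groups returns (stat 0, df 0, p 1); all values positive in both
groups drops the discrete component; positive values with (numerically)
zero within-group variance, or positives present in only one group, drop
the continuous component. Under a null with 60% detection and
gamma-distributed positive values at n = 100 vs 200, the empirical type-I
error at α = 0.05 is ≈ 0.05 and the p-value distribution is uniform by a
KS check (asserted in the acceptance tests).

**Fold change.** `log2FC = log2(mean(2^x − 1) + c) − log2(bg mean + c)`
with pseudocount c = 1, i.e. the difference of log2(linear mean + 1)
between foreground and background. This makes the RL score — log2 of the
product of linear fold changes — an exact sum of the two log2FCs, and is
always finite.

Strata with fewer than 3 cells (configurable) are emitted with p = 1 and
status `too_few_cells` rather than fitted: two points cannot support the
logistic and Gaussian fits. **Multiple testing**: Benjamini–Hochberg
step-up over the whole table — all genes × all (cell type, sample) strata
as one family — with a per-stratum family available behind a flag. No gene
pre-filtering is applied: fold-change and detection thresholds for entry
into testing are zero.

## Receptor–ligand scoring

The prior is subset at load time to directed edges with a known mode of
action (stimulation or inhibition); duplicates collapse to one edge. Mode
is carried through to the output but does not alter the score's sign,
since only subsetting, not sign handling, is defined for it. Edges are
evaluated in the ligand→receptor direction only: sender expresses the
ligand, receiver the receptor.

Per edge and per sample, `rl_score = ligand_log2fc + receptor_log2fc`
(ligand stats from the sender stratum, receptor stats from the receiver
stratum in the same sample). A group-aggregate record carries the
arithmetic mean of the per-sample scores; both are reported because
either view may be wanted for a heatmap. The significance flag is a
replicate-consistency filter: an edge is flagged only if **every** sample
of the group passes all four conditions — ligand p_adj < 0.01, receptor
p_adj < 0.01, ligand log2FC ≥ 0.5 (inclusive), receptor log2FC > 0
(exclusive). The receptor bound is zero, not 0.5. All edges are retained
in the output with the flag set or not; relaxing any threshold can only
add flags (monotonicity, tested).

## MxIF quantification

Each marker channel is thresholded into a binary mask (pixel positive
where intensity is strictly above the threshold). The threshold is either
fixed per channel or selected automatically by Otsu's bimodal-histogram
method; whichever is used is recorded in the mask's provenance, since
reproducibility requires the threshold be logged either way. A constant
channel under automatic selection is an error that suggests a fixed
threshold.

"Overlaying" the two marker masks of a CAF subtype is implemented as
**intersection** by default — the subtypes are defined by marker
co-expression (CAF1 = VIM⁺SMA⁺, CAF2 = PDGFRα⁺TNC⁺) — with union
available via a flag and recorded in provenance, since either reading of
an overlay is defensible. The tumor region is the thresholded β-catenin
mask used directly, without morphological cleanup by default.
Abundance = |CAF mask ∧ tumor mask| / |tumor mask|, which is invariant to
anything outside the tumor region and bounded in [0, 1]. Group
comparisons use the pooled-variance two-sample Student's t-test
(df = n₁ + n₂ − 2); zero pooled variance returns p = 1 when means agree
and p = 0 with a warning when they differ.

## Synthetic data

The count generator draws gene baselines log-normal around
`baseline_mean` (default 2 counts, log-sd 0.6), per-cell library-size
factors log-normal with unit mean (log-sd 0.35), and counts
NB(mean = baseline × cell factor × 2^planted_log2FC, size = 2). Dropout
is then applied as an extra zeroing step, logistic and decreasing in the
log2 NB mean (midpoint −6, slope 0.4), because the downstream hurdle test
assumes zero inflation beyond what NB sampling provides. The group/sample
layout defaults to 3 replicates for one condition and 2 for the other,
fully configurable. Identical seed and config give bit-identical outputs.

The standard study harness plants three ligands in the CAF2 sender and
three receptors in the tumor receiver at log2FC 2 across the three
replicate samples of one group, inside a 300-gene universe with 20 decoy
edges drawn between effect-free genes. The universe is deliberately large
relative to the planted genes: under per-cell normalization a planted
gene that is a large fraction of the transcriptome inflates its own
cells' totals and compositionally attenuates its fold change, which is an
artifact of small gene universes, not of real transcriptomes.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, gene–gene correlation, and any fit to real depth or dropout
profiles — the defaults are chosen for testability. Passing tests
therefore demonstrate correctness of the computations under the stated
model, not robustness to those artifacts.

The image generator paints rectangular or elliptical regions into named
channels at fixed intensity (max under overlap) over optional Gaussian
background noise (clipped at 0), recording the exact painted pixel set
per channel; analytic abundances derive from those sets.

## Numerical choices

* BH adjustment delegates to `statsmodels` and is verified elementwise
  against a brute-force step-up oracle to 1e-12.
* The Gaussian LR uses RSS ratios with an epsilon floor of 1e-12; RSS
  values are clipped at zero against catastrophic cancellation.
* The binomial LR uses `xlogy` so empty categories contribute 0·log 0 = 0.
* χ² with df = 0 is defined as p = 1.
* Seeds: every stochastic component takes a single seed; the study
  harness derives stage seeds via `SeedSequence.spawn`, keeping them
  below 2³¹.

## Problem sizes

The packaged study runs 4 cell types × 3 samples × 500 cells at 300
genes, with DE restricted to the 46-gene prior universe; null calibration
uses 1,000 replicates at n = 100 vs 200. These sizes give Monte-Carlo
error comfortably inside the asserted tolerances (e.g. ±0.3 on a planted
log2FC of 2) while keeping a full run in seconds.

## Known limitations

* The hurdle model fits no covariates beyond the group indicator; if the
  cellular detection rate confounds group membership the test inherits
  that bias.
* The consistency filter treats samples symmetrically; unbalanced designs
  where one replicate is tiny will fail edges through its flagged
  low-power strata, which is conservative by construction.
* Image quantification assumes thresholding is meaningful per channel; no
  illumination correction, registration, or segmentation is attempted.
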