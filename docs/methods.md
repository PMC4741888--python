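# Methods

`triostage` analyses matched trios of bulk RNA-seq samples — normal oral
mucosa (N), oral epithelial dysplasia (D) and the associated oral squamous
cell carcinoma (T) from the same patient — to separate transcriptional
events of dysplasia *formation* from events of *malignant transformation*.
This note records the models, the defaults and why, what the synthetic
cohorts do and do not emulate, and the numerical choices.

## Expression quantification and filtering

Counts are taken as given (gene-level fragment counts); FPKM is computed
from the count table itself:

    FPKM[g, s] = count[g, s] / (exonic_kb[g] × column_total[s] / 10⁶)

so that per sample Σ_g FPKM·length_kb = 10⁶ exactly. A gene is *expressed*
when its mean FPKM is ≥ 0.1 (inclusive) across the samples of at least one
tissue type. The "at least one tissue" (union) reading is a deliberate
choice — it yields a single expressed background shared by every
downstream stage, which is how a single background gene universe for
enrichment arises; the intersection reading is available via
`filter_expressed(..., mode="all")`.

A caveat on monotonicity: because the FPKM denominator is the column
total, raising one gene's count slightly lowers every other gene's FPKM.
The filter is monotone in a gene's *own* count (adding fragments to a gene
can never silence it) but not jointly across genes; the tests check the
former.

## Paired differential expression

Three pairwise contrasts are fitted on the expressed genes: NvD, DvT and
NvT, each restricted to patients carrying both tissues. Per gene the model
is a negative-binomial log-linear GLM

    log μ_gs = offset_s + patient_p(s) + β_g · condition_s,
    Var(y_gs) = μ_gs + φ_g μ_gs²

with `offset_s = log(TMM-scaled library size)`. The patient blocking
factors absorb whatever is shared within a patient — the entire point of
the matched design — and `β_g / ln 2` is the reported log2 fold change,
positive when expression is higher in the later disease stage.

Choices, in fitting order:

* **TMM normalisation** — reference sample = the one whose upper-quartile
  count fraction is closest to the cohort mean; 30% M-trim, 5% A-trim,
  precision-weighted mean of M values; factors rescaled to geometric
  mean 1.
* **Dispersion** — a Poisson fit of the full design supplies fitted means;
  φ_g comes from the moment identity Σ((y−μ)² − μ)/μ² over (S − P) residual
  degrees of freedom, clipped to [0, 10], then shrunk 50% toward the
  cohort median. The 50% pull toward a common value is a deliberately
  simple stabiliser standing in for full empirical-Bayes machinery; at 19
  pairs it is enough to keep the null calibrated (see below).
* **Testing** — likelihood-ratio test of the condition coefficient against
  χ²₁, two-sided; Benjamini–Hochberg across tested genes; primary DE
  threshold `p_adj ≤ 0.01`, with a secondary 0.10 flag reported alongside.
  The GLM-with-LRT route was chosen because it is the one NB testing
  scheme that accommodates a paired design directly.
* **Degenerate genes** — when one condition is all-zero the MLE diverges;
  those genes keep their LRT p (the deviance limit is finite; the linear
  predictor is clamped to ±30) but report a continuity-corrected fold
  change `log2((m₂+0.5)/(m₁+0.5))` of normalised condition means. Genes
  with no counts anywhere get p = 1, log2FC = 0.
* **Vectorisation** — every IRLS step is one dense (genes × samples) ×
  (samples × P²) product plus a batched P×P solve, so 10,000 genes × 38
  samples fit in ~2 s; iteration stops when all deviances change by < 1e-8
  (relative), cap 50.

Measured on all-null synthetic trios (10,000 genes, 19 patients, 50
replicates), the mean fraction of genes called DE at the 0.01 FDR is
~10⁻⁴, far inside the 1.5% acceptance band; planted 4-fold effects at
dispersion 0.05 are recovered with mean log2FC within [1.8, 2.2] and >80%
detection.

## Venn staging

A gene's DE-flag triple (NvD, DvT, NvT) places it in one of eight disjoint
classes. Stage labels read the classes under the progression model:
*early* = DE NvD but not DvT (dysplasia formation), *late* = DE DvT but
not NvD (malignant transformation), *consistent* = all three, *transient*
= NvD ∩ DvT without NvT (changed one way then back — the IL36G-like
pattern, flagged when the two fold changes are opposite-signed). The
early-event identity |NvD \ DvT| = |NvD-only| + |NvD∩NvT| holds by
construction and is asserted on arbitrary flag configurations.

## Enrichment and the cis-window control

Gene-set enrichment is the one-sided hypergeometric upper tail (equal to a
one-sided Fisher exact test), always computed after restricting the set to
the expressed background. The p-value is computed in-package: one
log-gamma evaluation at the modal tail term plus the exact pmf ratio
recurrence. This keeps relative error near machine precision even for
very small p; generic distribution `sf` routines lose ~1e-10–1e-6 relative
accuracy as |log p| grows, which matters when tests assert agreement with
an independent brute-force summation at 1e-10. Multi-set runs optionally
BH-adjust across sets; single-set calls report raw p.

The cis-window control asks whether genes flanking a clustered family
(default ±2,000,000 bp beyond the outermost family coordinates, ≥1 bp
overlap, boundaries inclusive) show the same coordinated regulation the
family shows; if they do, a copy-number event is the likelier cause. Two
read-outs per contrast: hypergeometric enrichment of DE genes among window
genes, and a one-sided binomial sign test for excess up-regulation among
the DE window genes. A window with no genes is reported "not evaluable"
rather than p = 1.

## Immune read-outs

* **Immune score** — a single-sample rank-enrichment score (ssGSEA-style)
  of an immune signature: within each sample genes are ordered by
  expression, the rank-weighted (weight = rank^0.25) ECDF of signature
  genes is compared with the plain ECDF of the rest, and the gap is summed
  over the ordering. The raw statistic is centred on its random-signature
  expectation (the rank weighting alone lifts the weighted ECDF), so null
  scores sit at 0. Being rank-based, the score is invariant to any
  strictly monotone within-sample transform. Per tissue, Pearson r (and
  its two-sided t-test p) against the pathologist's visual immune-cell
  percentage is reported. ≥10 matched signature genes are required.
* **Immunome** — per immune-cell-type marker set: members up-regulated at
  unadjusted p ≤ 0.01 (a per-gene screen, deliberately distinct from the
  FDR of the main DE calls) are counted against all up-regulated genes by
  the same one-sided Fisher machinery, significance at p ≤ 0.05. The same
  machinery applies unchanged to externally produced DE tables
  (`compare_external_de`), where the mean percent expression change of a
  set's DE members is `mean(2^log2FC − 1) × 100`.
* **CYT** — per sample, `log2((FPKM_GZMA + FPKM_PRF1)/2)` by default. This
  operational form is the log2 of the *arithmetic* mean even though the
  score is conventionally described as a geometric mean; the package
  reproduces the operational form and exposes the true geometric mean
  (`mode="true_geometric"`, 0.01 FPKM floor) as an alternative. Per
  patient, ΔCYT(N→D) and ΔCYT(N→T) use only patients with both samples;
  the cohort summary is mean ± s.e.m.

## PCA and gene ranking

PCA runs on log2(FPKM+1) of the expressed genes (optionally
protein-coding only), gene-centred but not unit-scaled — centring-only
preserves the contribution of expression magnitude to the loadings, which
is what a "weighting"-based gene ranking wants. Signs follow a
deterministic convention (largest-magnitude loading per PC positive).
Genes are ranked by the mean |loading| over a chosen PC list; the top
⌈fraction × n⌉ (default 5%) are flagged, ties broken by gene id. Because
"which PCs separate the groups" is a by-eye biplot judgement in practice,
`separating_pcs` automates it by ranking PCs on the one-way ANOVA F of
their scores grouped by tissue. The top-fraction universe (all expressed
vs protein-coding-only genes) is a parameter, not a constant.

## Co-expression network

Pairwise Pearson correlation (Spearman optional) of log2(FPKM+1) across
all samples. Thresholds come from a random sample of
`round(0.01 × C(G,2))` distinct unordered pairs (drawn by rejection
sampling of flat pair indices, decoded by inverting the triangular row
index — no G² materialisation): the retained-edge thresholds are the
nearest-rank empirical quantiles of the sampled correlations at the tail
fraction (default 0.0005%) and its complement. Retention is inclusive
(r ≥ upper or r ≤ lower). Constant genes correlate 0 with everything, with
a warning. The full graph is built blockwise (default 2,000-gene blocks)
so memory stays bounded; nodes carry biotype and Venn class for Cytoscape
colouring, via GraphML or SIF + node-attribute sidecar.

Subclusters are connected components of the r > 0.95 (strict) positive
subgraph — the unit of guilt-by-association annotation. Antisense genes
are reported with the correlation to their sense partner and whether the
two share a subcluster.

Note on desk-scale verification of the threshold estimator: a 1% sample
of C(1000,2) is only ~5,000 pairs, so an extreme tail like 0.0005% (which
at study scale is order statistic ~22 of 4.4 million) is simply not
estimable from it. The oracle tests therefore evaluate the estimator at a
2% tail (order statistic ~100 of the sample) on a cohort without planted
correlation structure, where the sampled quantiles sit within ±0.02 of
full enumeration; full-enumeration samples are additionally checked to
match brute-force quantiles exactly.

## The synthetic cohort generator

`simulate_trios` emulates the matched-trio study design: 19 patients ×
three tissues, NB counts with variance m + φm² (φ uniform in [0.05, 0.2]
per gene), library sizes uniform in [0.8, 1.2] × 10⁶, and log-normal
**gene-specific patient effects** (s.d. 0.5 on the natural-log scale)
shared across a patient's three samples. The gene-specificity matters: a
patient-global multiplier would be indistinguishable from library size and
normalised away, leaving nothing for the paired design to remove.

Planted structure, with defaults:

* Stage-effect classes (early/late/consistent up/down, transient up-down)
  at |log2FC| = 2 (4-fold), occupying ~8.4% of genes in total — enough DE
  signal to exercise the Venn machinery without dominating the
  transcriptome.
* Five immune cell types × 15 marker genes. Markers carry **no** intrinsic
  stage effect; their mean is `baseline × (0.1 + 5 × infiltration
  fraction)`, so all their DE signal is infiltration-driven — precisely
  the confounder the immunome reads out. Default infiltration plants a
  cytotoxic wave peaking at dysplasia (3% → 25% → 8%) and an inflammatory
  (macrophage/neutrophil) wave peaking at tumour, the pattern of an
  immune-surveillance-then-inflammation progression. The first two
  cytotoxic markers are named GZMA and PRF1 so the CYT score applies
  as-is. The pathologist's immune percentage is 100 × total infiltration
  plus Gaussian noise (s.d. 5 points), truncated to [0, 100].
* A clustered early-up family (HOX-like) packed on its own chromosome,
  with 40 null genes strewn through the ±2 Mb flanks so the cis-window
  control has genuine neighbours; 20% of later-stage effect genes are
  typed lincRNA so coding-only and all-gene PCA genuinely differ.
* Antisense genes are noisy scalings of their partner's counts with the
  noise budget set on the library-normalised scale to hit the target
  log-scale correlation (default 0.98) on the scale the network analysis
  actually correlates; measured mean achieved correlation ≈ 0.98.
* A 2% slice of genes is planted below the FPKM filter to exercise it.

What the generator does **not** emulate: FFPE degradation, strandedness
artefacts, multi-mapping ambiguity, correlated co-regulation beyond the
planted modules, HPV status, or compositional effects of extreme
high-expressors. Passing tests therefore demonstrate that the pipeline's
inference machinery is correct and calibrated under its own model
assumptions — not that those assumptions hold in any particular FFPE
cohort.

## Problem sizes used in the test and acceptance runs

Monte Carlo checks run at the emulated design size (19 patients) with gene
counts chosen per question: 10,000 genes × 50 replicates for null FDR
calibration, 4,000 genes for effect/stage recovery, 1,500 genes × 50
replicates for the immunome direction read-out, 1,000-gene instances for
the threshold oracle, 200 genes for brute-force network equality. The
vectorised GLM makes each 10,000-gene contrast a ~2–4 s operation.

## Known limitations

* The NB GLM's χ²₁ asymptotics are mildly anticonservative in the raw p
  tail at 19 pairs (~2% of null genes at p ≤ 0.01); BH at FDR 0.01 remains
  strongly conservative under the null. Exact-test or quasi-likelihood
  variants are out of scope.
* TMM assumes most genes are not DE; cohorts with global shifts violate it.
* The immune score is an in-spirit rank-enrichment reimplementation of
  signature scoring, not a port of any published tool's gene lists or
  normalisation; absolute score values are not comparable across tools.
* Hypergeometric enrichment treats genes as exchangeable; no length or
  expression bias correction.
* `compare_external_de` trusts the external table's p-values and universe.
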