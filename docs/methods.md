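# Methods

`hmrisk` implements a tumor-vs-normal chromatin analysis chain: quantify
histone-modification (HM) ChIP signal around transcription start sites,
rank marks by how well their signal changes predict expression changes,
select genes with sample-specific mark levels by Shannon entropy, and build
a Cox proportional-hazards risk score over candidate driver genes. A
synthetic-data generator supplies every input with the statistical structure
the analysis assumes, so the whole chain runs and is tested without any
external download.

## Signal and expression quantification

Expression from cell-line read placements uses the RPKM convention

    L_j = n_j * 1e9 / (N * l_j)

with `n_j` the reads whose **midpoint** falls in an exon of gene *j*, `N`
the library size, and `l_j` the exon-model length. Cohort matrices (TPM or
log-scale expression) are accepted as-is; the formula applies only to read
data.

Mark signal is quantified on a fixed grid: the 10 kb window centred on the
TSS is cut into 100 bins of 100 bp, ordered 5'→3' along the gene (reversed
genomic order on the minus strand, so "bin 60" always means "1 kb into the
gene body"). Per bin,

    H = n_bin * 1e9 / (N_mark * l_bin),      l_bin = 100 bp.

Reads are assigned to the bin containing their midpoint; assignment by full
overlap would double-count reads spanning bin edges, and the midpoint rule
makes the per-gene bin counts sum to at most the reads in the window (a
tested invariant). Reads on a different chromosome than the gene are never
counted. Windows that would extend past the chromosome start are clipped at
zero and flagged.

Tumor/normal signal change per (mark, gene, bin) is
`log2((mean_t + eps) / (mean_n + eps))` with means over replicates and a
pseudocount `eps` (default 1.0 signal unit) because the ratio is undefined
at zero; `eps` is configurable and enters only the ratio.

## Differential expression

Genes are classed up/down when `|log2 FC| > 1` and a two-sided p < 0.01
(both thresholds configurable). Two statistics are provided:

* `welch` (pipeline default): the Welch two-sample t statistic
  `(mean_t - mean_n) / sqrt(s2_t/N_t + s2_n/N_n)` with Satterthwaite df.
* `as_printed`: the same standard error under a fold-change-ratio numerator,
  mapped through the normal tail. Some published workflows define their
  score exactly this way; it is kept verbatim for comparability. Note the
  ratio form is not sign-symmetric — swapping condition labels does not
  negate it — which is why `welch` is the default and the symmetry property
  is only guaranteed there.

Zero variance in both groups (e.g. noise-free fixtures) is floored at a
small constant (`var_floor`, default 1e-8) so the statistic stays finite.
The pseudocount enters the fold change, never the variance terms.

## Mark importance

Up- vs down-regulated DEGs are classified from signal-change features (one
column per mark × bin) by a random forest (500 trees by default, sqrt(p)
features per split, fixed seed). Every gene receives an out-of-training
score — the fraction of trees voting "up" — under one of three resampling
schemes:

* `repeated_split` (default): 10 repetitions of a stratified random
  30%-train / 70%-test split, averaging each gene's held-out scores; if a
  gene is never held out, one final fit trained only on already-scored genes
  closes the gap.
* `kfold`: stratified 10-fold CV.
* `oob`: one forest on all genes, scored by out-of-bag vote fractions. This
  is the classic randomForest construction and costs a single fit per
  model, so the exhaustive sweeps use it.

The AUC is the trapezoidal area under the ROC of the pooled scores, which
equals the Mann–Whitney U statistic of up-scores vs down-scores divided by
(N_up × N_down) — asserted to 1e-10 against an independent implementation.
Sensitivity and specificity at the 0.5 vote threshold are reported
alongside (1 − misclassified/up-count and the mirror image).

Three analyses build on the classifier:

* **Subset sweep** — every non-empty subset of the k marks (2^k − 1 = 2047
  models for the 11-mark panel), with the best-AUC-per-size envelope curve.
* **Qualifying-subset frequencies** — among fixed-size subsets whose AUC
  exceeds 95% of the full-panel model's, the percentage containing each
  mark.
* **Per-bin rank map** — one model per bin on the k mark features at that
  bin; marks ranked 1..k by permutation importance (mean decrease in
  held-out AUC over 5 permutations), ties broken by mark name so each
  column is a deterministic permutation. Permutation importance is the
  classification analogue of the IncMSE measure used with regression
  forests.

## Entropy selection

For a chosen mark, a gene's per-sample signal is the sum over the 100 bins.
Signals are standardised per sample as `SH = (H − H_min) / H_max` with the
extrema taken over genes within each sample (that is what the per-sample
subscript implies; dividing by the range `H_max − H_min` — classical
min-max — is available as an option, and extrema per gene as another).
The standardised values are normalised across the M samples into a
distribution P, scored by Shannon entropy `E = −Σ P log2 P` (with
0·log2 0 ≡ 0), and genes with E below a threshold (default 1.549) for
either H3K36me3 or H3K79me2 are selected, annotated with the triggering
mark(s). Genes whose standardised signal is zero in every sample cannot be
distinguished and are assigned the maximal entropy log2(M) with a flag.

Two caveats are surfaced rather than hidden. With M = 2 samples the
entropy is capped at 1 bit, so the default threshold selects every gene (a
warning is emitted). And because the per-sample maximum in tumor samples is
inflated by whichever gene gained the most signal, the selector is
asymmetric: genes that *lose* the mark in tumor reach low entropy easily,
while genes that *gain* it must out-gain the most extreme gainer. This is a
property of the standardisation as defined, not of the implementation.
Relatedly, how many genes the stage passes depends strongly on the tail of
the per-sample signal distribution (heavier tails shrink all standardised
signals and lower entropies across the board), so in practice the candidate
funnel's selectivity comes from the intersection with the DEG set and the
expression filter as much as from the entropy threshold itself.

## Survival modelling

The candidate funnel intersects the entropy-selected genes with the DEGs
and keeps genes expressed (> 0) in more than 90% of tumor samples. Each
candidate is screened by a univariate Cox fit (Efron tie handling
throughout, via lifelines); genes with p < 0.05 proceed to an L1-penalised
Cox path (scikit-survival's Coxnet). The penalty is chosen by 10-fold
cross-validated partial-likelihood deviance, computed as the
full-minus-train log partial likelihood of fold-trained coefficients (the
Verweij–van Houwelingen construction); genes with nonzero coefficients at
the chosen penalty enter a joint Cox fit, optionally reduced to covariates
with p < 0.05. If the screen leaves a single gene the LASSO step is skipped
(an L1 path over one covariate cannot select) and the gene goes straight to
the joint fit.

The risk score is the fitted linear predictor `RS = Σ coef_j · x_j` over
the model genes, on the expression scale the model was fit on (no
standardisation by default; z-scoring is available). Patients are split at
the median RS with ties to the low group (deterministic split; group sizes
differ by at most 1 when scores are distinct). Group survival is compared
by Kaplan–Meier curves and a two-sided log-rank test; a group with zero
events flags the p-value as unreliable.

Time-dependent ROC uses the cumulative-case / dynamic-control definition:
at horizon t, cases are subjects with an event by t, controls those still
at risk beyond t. The default estimator weights cases by the inverse
Kaplan–Meier censoring survival G(T−) (Uno's IPCW form; cross-checked in a
test against scikit-survival's independent implementation to 1e-6). A
nearest-neighbour smoothed estimator in the style of the survivalROC
package (span 0.25·n^(−0.2)) is the alternative mode.

## Synthetic data

The generator emulates the study design end to end; defaults are the study
conditions used by the tests.

* **Gene models** — non-overlapping genes on one chromosome, mixed strands,
  1–10 exons, spans 2–15 kb (300 genes by default).
* **Expression truth** — 20% up- and 20% down-regulated genes with
  `log2 FC ~ ±Uniform(1.5, 4)`, others ~ N(0, 0.15); baselines
  Uniform(5, 9) on the log2 scale (well-expressed genes, so planted down
  shifts rarely clip cohort values at zero). Cell-line tables carry 4
  replicates per condition with log-normal replicate noise (sd 0.25 in
  log2); four replicates are the smallest design in which a t-based screen
  at p < 0.01 can recover the planted classes it is meant to recover.
* **ChIP reads** — 11 marks with the panel's usual names; promoter-peaked
  profiles (Gaussian at the TSS, bins 45–55) for H2AFZ, H3K4me1/2/3,
  H3K9ac, H3K27ac; a gene-body ramp over bins 51–100 for H3K36me3 and
  H3K79me2; broad/flat for H3K9me3, H3K27me3, H4K20me1. Per-gene mark
  intensities are lognormal with sigma 1.0 (gene-level ChIP signal is
  heavy-tailed). Per-bin counts are negative binomial (dispersion 0.3;
  ChIP counts are overdispersed), two replicates per condition, read
  midpoints uniform within the generating bin. For the causal marks
  (default H3K36me3, H3K79me2) the tumor gene-body intensity is scaled by
  `2^(effect × log2FC)` of the gene's planted expression change, so
  expression change is driven by exactly those marks.
* **Cohort** — 400 samples (10% normal) on a log-expression scale with
  sd 1 sample noise; a small fraction of genes gets zeros in 15% of tumor
  samples to exercise the expressed-in-most-samples filter. Nine driver
  genes carry planted Cox coefficients (defaults with the magnitudes of a
  published nine-gene signature, ~|0.1–0.5|); drivers are drawn from the
  planted DEGs with a 6:3 down/up split, matching the direction mix of
  elongation-mark changes across such signatures (most drivers lose the
  gene-body marks in tumor). Survival times are exponential with hazard
  `λ0 · exp(η)` (centred linear predictor, median survival 5 years);
  censoring times are uniform on [0, τ] with τ bisected so the censored
  fraction matches the configured 30%.

Everything is deterministic under the master seed (two runs produce
byte-identical files), and the planted truths (classes, fold changes,
causal marks, driver coefficients) are written to a JSON sidecar.

What the generator does **not** model: input/IgG background structure,
fragment-length effects, copy-number confounding, correlated mark
co-occurrence beyond the planted coupling, batch effects, or non-
proportional hazards. Passing tests therefore demonstrate that the chain
recovers planted structure under its own assumptions, not performance on
real cohorts.

## Problem sizes and numerical choices

The default test scale is 300 genes, 2 ChIP replicates/condition/mark, and
a 400-patient cohort; the repeated-seed end-to-end check runs at 120 genes
per seed, coefficient-recovery at n = 1000 patients, and the exhaustive
2047-subset sweep at 100 trees with out-of-bag scoring. Sub-seeds for
independent components are derived from the master seed via numpy
SeedSequence spawning; per-subset forest seeds add a CRC32 of the subset
name so subset results do not depend on sweep order. Ties: rank ties broken
by mark name; median-split ties to the low-risk group; Cox partial-
likelihood ties by Efron's method; the CV deviance grid uses the Coxnet
path's own alpha grid (50 points, alpha_min_ratio 0.01).

## Known limitations

* The entropy selector's asymmetry (above) means gain-of-mark genes are
  under-selected relative to loss-of-mark genes at few samples; with more
  samples per condition the effect shrinks.
* The univariate Cox screen is marginal: with several simultaneous drivers
  its coefficients are attenuated, so weak drivers (|coef| ≈ 0.1 at
  expression sd 1, n = 400) are frequently missed — visible in the
  acceptance run's model-gene counts.
* The `as_printed` DEG statistic is a ratio, not a mean difference; its
  p-values are not calibrated and the mode exists for comparability only.
* BED12 names are interpreted as `gene|transcript`; GTF requires gene_id
  and transcript_id attributes.
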