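# Methods

## Problem and model

A draft eukaryotic assembly is a mixture of target-organism scaffolds and
contaminants. `decontree` classifies each scaffold from eight measurable
features — length, GC, mean DNA/RNA depth, DNA/RNA breadth of coverage,
and aligned-read GC for both libraries — using CART decision trees trained
on the subset of scaffolds that BLAST can label by genus. Scaffolds with
no BLAST hit are excluded from training and testing but are always
classified by the fitted model; that is the point of the method.

Trees are binary and axis-aligned. At each node every candidate predictor
is searched exhaustively; candidate thresholds are midpoints between
consecutive distinct sorted values, and a value equal to the threshold
routes left. Splits are scored by n-weighted mean child Gini impurity
(default) or by information gain in bits; ties break toward the earlier
predictor in the canonical column order, then the lower threshold. A node
stops splitting when it is pure, children would fall below `min_leaf`
(default 1), or a tree-wide `max_splits` budget (counted breadth-first) is
exhausted. There is no pruning: variance is handled by aggregation.

When no single split reduces impurity at an impure node but distinct
predictor values remain, the learner admits the best zero-gain split and
continues. Without this fallback, XOR-patterned regions — separable by a
pair of splits though no single split helps — would terminate as impure
leaves, and training error on consistent data would not reach zero.

Leaves store class proportions as posterior estimates P̂(k|x) and classify
by expected-cost minimization; the cost matrix defaults to 0/1, and ties
go to the target class. Ensembles:

* **Bagging** — B bootstrap resamples of size n, one fully grown tree
  each; the target score is the mean leaf posterior, thresholded at 0.5
  with ties classified as target (the sensitivity-favoring choice; in
  decontamination a discarded true-target scaffold is the costlier
  mistake). B defaults to 100, past the point where between-draw variance
  plateaus on the synthetic regimes.
* **Random forest** — bagging with a fresh random subset of m = 4 of the
  p = 8 predictors at every split (per-split sampling, the Breiman
  convention; per-tree sampling is available behind a flag). At m = p and
  a shared bootstrap stream it reproduces bagging tree for tree, which is
  asserted in the tests.
* **Boosting** — squared-error residual boosting on the 0/1 target
  indicator: F₀ is the base rate, each of 10 stages fits a ≤ 2-split
  regression tree to r = y − F and updates F ← F + 0.01·tree; scores are
  clipped to [0, 1].

Variable importance per tree sums, over each predictor's splits,
(n_node/n_root)·(G_parent − w_L·G_L − w_R·G_R); ensemble importance is the
tree mean normalized to sum to one. An unweighted literal variant
(G_parent − G_left − G_right, which can be negative) is available behind
`weighted=False`; the weighted form is the default because importance is
used for ranking and should be non-negative.

## Predictor extraction

Length counts all residues including N; GC is (G+C)/(A+C+G+T), so
ambiguous bases dilute neither numerator nor denominator. A scaffold of
only ambiguous bases gets GC 0 with a warning flag. From SAM/BAM, depth at
a position counts retained alignments whose CIGAR consumes it (M/=/X/D);
secondary, supplementary, unmapped and QC-fail records are dropped, paired
reads must be properly paired (configurable), and whole read groups can be
excluded from coverage — the intended use is mate-pair libraries, whose
chimeric inserts distort depth. Breadth is the fraction of positions at
depth ≥ 1 (the threshold is exposed in the filter options; 1 is the least
arbitrary choice). Aligned-read GC is computed over the soft-clip-trimmed
read sequences of retained alignments by default; a flag restricts it to
reference-aligned bases, since "GC of the reads aligned" is ambiguous
between the two. Scaffolds with no RNA evidence get zero-valued RNA
columns: absence of transcription is signal, not missing data.

Alignment evidence can also enter as TSV, in two dialects distinguished by
header: a per-scaffold summary (`scaffold_id, mean_depth, breadth,
aligned_read_gc`) and a per-base table (`scaffold_id, pos, depth` with an
optional constant `read_gc` column, 1-based positions validated against
scaffold length). The TSV path exists so that model-level work and tests
never require an aligner.

## Labels

Each scaffold's best BLASTn hit is the one with maximal bitscore, ties
broken by minimal e-value, then input order. The genus is the first
whitespace token of the subject taxon text, compared case-insensitively
with the configured target genus. Curation overrides are case-insensitive
substrings matched against the full taxon text, with contaminant
overrides taking precedence over target overrides over the genus rule; a
hit matching overrides on both lists raises as ambiguous curation. Labels
are taken as given — database contamination makes them noisy, and no
denoising is attempted. Train/test splits sample labeled ids uniformly
without replacement (|train| = round(fraction·|labeled|)); stratification
is off by default and available behind a flag.

## Synthetic regimes

The generator draws the eight predictors directly from class-conditional
distributions rather than simulating reads and re-assembling: the
classifier consumes per-scaffold features, so emulating their joint
distribution is the faithful desk-scale stand-in, while the toy file
bundle still exercises the real FASTA/TSV/BLAST parsers. Per scaffold:
length ~ log-normal (floored at 250 bp); GC ~ uniform on the class range;
DNA depth ~ gamma parameterized by mean/sd; RNA breadth ~ beta with a
class-specific mean (gene density) and concentration; RNA depth = breadth
× log-normal expression (median 30× coverage, σ = 0.5); DNA breadth =
(1 − e^(−0.8·depth)) × a beta-distributed alignability factor; read GC =
scaffold GC plus N(0, 0.01) noise (RNA read GC shifted +0.02 for the
GC-richer coding fraction), clipped to [0, 1].

Three shipped presets (editable YAML under `decontree/presets/`):

* `separable` — 100×-coverage target, GC 24–48%, gene-sparse (RNA-breadth
  mean 0.25) vs a 20×-coverage, GC 50–69%, gene-dense (0.85) microbial
  contaminant, 1000 scaffolds per class.
* `overlapping` — contaminant GC 23–53% inside the target's 24–72%, DNA
  depth identical (100× ± 20) for both classes. The contaminant is a
  75/25 mixture: a gene-dense majority (RNA-breadth mean 0.70) plus a
  minority transcribing at host-like levels (0.25) whose DNA breadth is
  low and patchy (alignability mean 0.60) — fragmented, under-assembled
  contaminant sequence. The mixture matters: with a single wide-gap RNA
  contrast, a handful of training scaffolds would already saturate
  accuracy and the training-fraction response real datasets show could
  not appear.
* `empirical_like` — 3:1 target:contaminant with a low-coverage wide-GC
  bacterial component and a high-GC component at target-like coverage,
  1% label noise and an 8% no-hit fraction.

The BLAST-labeling process marks each scaffold unknown with probability
`unknown_fraction` and flips surviving labels with `mislabel_rate`, both
per-preset. What the generator does **not** emulate: read-level error
models, insert-size and chimera artifacts, repeat-driven coverage spikes,
assembly fragmentation correlated across features, and phylogenetically
structured label error. Passing tests therefore demonstrate correctness
of the machinery and recoverability of feature-level signal, not
performance on any particular real assembly.

## Evaluation

Target scaffolds are positives: sensitivity = TP/(TP+FN) is target
retained, specificity = TN/(TN+FP) contaminant removed, error the
misclassified fraction of the labeled test set, accuracy = 1 − error. A
zero-denominator metric is reported as undefined, never silently 0. The
training-fraction sweep re-splits and refits per (fraction, replicate);
the predictor-subset sweep ranks predictors once by the Gini importance
of a full-predictor bagged model on a seed-fixed 50% split (re-ranking
per replicate would conflate ranking noise with subset effects) and then
evaluates top-k models for k = 2..8. Replicate seeds derive from the
master seed as SeedSequence([master, axis_index, replicate]), so any
replicate is individually reproducible; per-replicate records are kept so
aggregates can always be recomputed.

## Benchmarks and problem sizes

`scripts/acceptance.py` and the heavier tests run: the overlapping regime
at 2000 scaffolds × 10 seeds (bagged 8-predictor accuracy; 2-predictor
tree error), the separable regime at 4000 scaffolds × 10 seeds (minimum
of the three metrics), 100 training draws for the variance comparison at
1000 scaffolds, and a 20-replicate training-fraction sweep at 2000
scaffolds with B = 30. These sizes give stable means (metric standard
errors well under a percentage point) while a full run completes in well
under a minute on one core. On the separable preset the prescribed GC
ranges are disjoint, so single trees are already exact and the variance
comparison holds degenerately (0 ≤ 0).

## Numerical conventions and degenerate inputs

0·log₂0 ≡ 0 and an empty count vector has zero entropy and zero Gini;
proportions must sum to 1 within 1e-9; split improvements are compared
with a 1e-12 tolerance; information gain of every accepted split is ≥ 0
up to that tolerance. Empty FASTA, zero-length sequences, alignments to
unknown references, depth positions outside the scaffold, duplicate
scaffold ids, an all-unknown label set and single-class label sets all
raise with specific messages (the pipeline maps the last three input
failures to exit codes 3/4/5). A bootstrap resample containing one class
yields a majority stump, which is valid; a sweep replicate whose training
draw lacks a class is recorded as failed and excluded from aggregates
with a count.

## Limitations

Genuine horizontally transferred sequence looks foreign by construction
and risks removal; no HGT-specific safeguard exists beyond the model
using coverage/transcription evidence rather than homology. Labels
inherit database contamination. The default decision threshold favors
sensitivity; users wanting stricter contaminant removal should lower the
keep threshold or supply an asymmetric cost matrix. Tree growth to purity
means single-tree models overfit noisy regions — by design, since
aggregation is the variance control.
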