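# Methods

## Problem statement and model

Fold recognition is framed as binary classification of ordered
(target, template) protein pairs. Each pair is described by a real-valued
similarity vector **v**; the positive class means the two proteins share a
structural fold at the family, superfamily or fold level of a SCOP-style
hierarchy, and the negative class (the overwhelming majority) means they do
not. A random forest of T trees is trained on labelled pairs; at prediction
time each tree emits the class fractions of the leaf reached by **v**, the
forest averages them, P(c|**v**) = (1/T) Σ\_t P\_t(c|**v**), and a target's
templates are ranked by P(same fold|**v**). Recognition quality is the
fraction of targets whose correct template is ranked first (top-1) or in
the top five (top-5), per level.

## Decision trees and the forest

Trees are grown by greedy recursive partitioning maximising information
gain (entropy in bits). Split candidates are midpoints between consecutive
distinct sorted values of a feature; samples with value ≤ threshold go
left, and a value exactly on the threshold goes left. A node becomes a leaf
when it is pure, holds fewer than 2·`min_leaf` samples, reaches
`max_depth`, or no candidate split has positive gain (gains below 1e-12
are treated as zero). Leaves store raw class fractions — no Laplace
smoothing — so the forest average is exactly the mean of observed leaf
fractions. Ties in gain keep the lowest feature index, then the lowest
threshold, making training deterministic.

Forest randomisation follows the classic recipe: each tree trains on a
bootstrap replicate of the n training pairs, and at every split a fresh
random subset of ⌈√p⌉ of the p features is considered
(`feature_sampling="per_split"`). A `per_tree` mode is also provided, in
which each tree is restricted once to a fixed random subset; the two modes
correspond to the two readings of "a random subset of features per tree"
found in the literature, and neither is claimed to dominate. Tree t draws
its bootstrap sample, feature subsets and split-sampling stream from an
independent RNG stream derived from (seed, t), so training is reproducible
and order-independent. An exact 0.5 probability tie predicts the negative
class — the conservative choice on data where negatives outnumber
positives by two orders of magnitude. Defaults: 500 trees (experiments in
this repository use 100 for speed; the comparison against a single tree is
insensitive to this), bootstrap on, `min_leaf` 1, unlimited depth.

The tree grower and the alignment matrix fill are numba-compiled; both are
exact implementations of the stated recurrences, not approximations.

## Pairwise features

The default feature vector has 21 entries in five categories; all
positions are 0-based and the canonical order is the output of
`foldrec.feature_names()`.

1. **Composition kernels (6).** Monomer (20) and dimer (400) relative
   frequencies compared with cosine similarity, Pearson correlation
   (defined as 0 when either vector is constant, since a constant
   composition carries no correlation signal) and a Gaussian kernel
   exp(−γ‖u−v‖²) with γ = 1/d for a length-d vector — a scale-free
   default; the bandwidth used by the original feature generators is
   unpublished. Ambiguity codes (B, Z, J, X, U, O) contribute uniformly
   over their ambiguity sets.
2. **Sequence–sequence alignment (4).** Global and local affine-gap
   alignment scores, raw and divided by the shorter sequence length.
   BLOSUM62, gap open −11, gap extend −1 (BLAST conventions); a gap of
   length g costs open + (g−1)·extend. Traceback ties prefer
   diagonal > up > left, so aligned coordinates are deterministic.
3. **Sequence–profile alignment (4 + indicator).** Each protein's profile
   aligned to the other's sequence, both directions. Profiles are
   per-column relative frequencies from the protein's MSA (first row =
   the protein's own sequence; columns where the reference row has a gap
   are dropped; gaps in other rows are excluded from counts) smoothed
   with a pseudocount of 0.01 per residue. Matching column c to residue r
   scores log2(c[r]/(1/20)) — log-odds against a uniform background.
4. **Profile–profile alignment (2 + indicator).** Column pair (c, d)
   scores log2((c·d)/(b·b)) with uniform background b, i.e. the
   dot-product profile–profile score.
5. **Structural compatibility (one per track + indicator).** The fraction
   of aligned positions whose predicted structural states agree (3-state
   secondary structure H/E/C and 2-state accessibility e/b by default),
   evaluated on the profile–profile global alignment; when either protein
   lacks an MSA the sequence global alignment is used as the base
   instead, and only missing tracks trigger imputation.

Missing inputs never abort featurization: affected features are imputed to
0 and a per-category binary "was imputed" indicator is appended, which
tree ensembles handle naturally. The published systems this mirrors used
84 features produced by ten external alignment and structure-prediction
programs; this package deliberately computes self-contained analogues in
the same categories, so absolute sensitivities are not comparable to
published numbers — the protocol, contrasts and orderings are.

## Evaluation protocol

Targets are shuffled by seed and dealt round-robin into 10 folds, so fold
sizes differ by at most one target and every pair follows its target.
Training pairs for a fold exclude any pair whose target *or template* is a
test-fold target (template leakage removal). Training negatives can be
subsampled to ⌊ratio · n\_pos⌋ without replacement; positives and test
pairs are never touched, and a ratio at or above the available negatives
keeps the original distribution. Grouping by target makes exactly equal
pair counts per fold impossible; equal-in-targets is the chosen reading.

Sensitivity uses the standard exclusion convention: evaluating the
superfamily level removes family-related templates from the ranking
first; the fold level removes family- and superfamily-related templates.
Eligible targets per level are those with at least one template related
at exactly that level, so a protein can be eligible at several levels
(counts per level can sum to more than the number of proteins). Ranking
ties break lexicographically on template id. Counts are pooled over all
folds and percentages computed from pooled counts; the pair error rate is
the pooled misclassification percentage at the 0.5 threshold. Specificity
is not part of the reported surface.

Two methodological sweeps share a single CV plan: one cross-validation
per training ratio (`imbalance_sweep`) and one per feature-count prefix
of the canonical feature order (`feature_count_sweep`).

## Synthetic benchmark

Each structural fold draws an independent uniform ancestor sequence and
per-track structural strings. Superfamily ancestors mutate the fold
ancestor at rate d(fold) − d(superfamily), family ancestors mutate those
at d(superfamily) − d(family), and leaf proteins mutate family ancestors
at d(family), where d is the per-level divergence map — so expected
divergence from the common ancestor grows with relationship depth.
Substitutions are uniform over the 19 alternative residues (no
substitution-matrix bias: the forest needs an identity gradient, not
realistic residue statistics). Structural strings are inherited from the
fold ancestor with independent per-position flips at `track_noise`; MSAs
are `msa_depth` noisy copies of each leaf at `msa_noise`. An optional
indel rate (default 0) applies joint insertions/deletions to a leaf and
its tracks, keeping them columnwise aligned.

Defaults (frozen as the package's standard conditions): 10 folds × 2
superfamilies × 2 families × U{1..4} proteins (~100 proteins, ~10,000
ordered pairs, negatives:positives ≈ 10:1), sequence length 60,
divergence {family 0.25, superfamily 0.62, fold 0.92}, `track_noise`
0.40, `msa_noise` 0.10. These were calibrated once so that the generator
realises the structure it is meant to emulate, and then frozen: mean
pairwise identity ≈ 0.56 / 0.22 / 0.13 for family / superfamily / fold
pairs against a 0.05 random background, placing fold-level pairs in the
twilight zone, and recognition difficulty increasing monotonically down
the hierarchy (top-1 roughly 85 / 77 / 57 at the default seed). With
cleaner structural tracks the fold level saturates and the gradient
inverts, which is qualitatively wrong for what the benchmark represents.
A `twilight` preset (family divergence 0.60) pushes *every* pair below
40% identity, emulating benchmarks curated to exclude easy matches.

What the generator does **not** emulate: realistic residue statistics and
indel structure, alignment-derived (rather than noise-derived) MSAs,
fold-size distributions of real classifications, and — because the
native class ratio at ~100 proteins is ≈10:1 rather than ≈127:1 —
training-ratio sweeps at 25:1 and above all cap at "keep every negative"
and thus coincide exactly. Passing tests therefore demonstrate protocol
correctness and qualitative orderings, not real-data performance.

One desk-scale artifact is worth knowing: structural tracks are shared
fold-wide, so at the superfamily level the excluded-ranking competitors
(fold-level relatives) carry the same structural signal as the correct
superfamily templates, and with some generator seeds superfamily top-1
can dip relative to its position in real benchmarks. The family-versus-
fold contrast — the headline difficulty gradient — is robust across
seeds.

## Numerical choices and degenerate inputs

* Alignment scores are exact dynamic programming (Gotoh three-matrix
  recurrences); local scores are floored at 0 and an empty local optimum
  returns no aligned pairs. Gap penalties must be ≤ 0.
* Midpoint thresholds that round onto the upper neighbouring value fall
  back to the lower value, keeping the ≤-threshold partition consistent
  with the split scan.
* Entropy of an all-zero count vector, alignment of an empty sequence or
  profile, ranking with no scored templates, subsampling with no
  positives, and sensitivity with no eligible targets all raise
  `ValueError` with a specific message rather than returning a default.
* A dataset with zero positives reports an infinite imbalance ratio; the
  exact ratio is stored and the conventional rounded form (e.g. 127:1) is
  derived from it for display.
* Model files are self-describing JSON; floats round-trip exactly, so
  save → load → predict is bit-identical and re-saving reproduces the
  file byte for byte.

## Problem sizes used by the test suite and acceptance script

The repository's experiments run on the ~100-protein default benchmark:
10-fold CV with 100-tree forests for the forest-versus-tree and
difficulty-gradient checks (ten seeds), 30-tree forests for the ratio and
feature-count sweeps. These sizes keep a full run in minutes while leaving
every contrast of interest (forest vs tree, level ordering, ratio
stability, feature-count effect) statistically visible; the package
itself has no scale-specific code paths.
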