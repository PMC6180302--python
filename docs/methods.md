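# Methods

This note documents the models and procedures implemented in `ccmscreen`,
their assumptions, the parameters that matter, and the design choices made
where the underlying methods descriptions left the design open.

## Fingerprints and compound identity

Structures are read either from a minimal SMILES subset (organic-subset and
bracket atoms, single/double/triple bonds, branches, ring closures, dot
disconnection; no aromaticity perception, stereochemistry or tautomer
handling) or as precomputed feature-set fingerprints via TSV pass-through.
The pass-through is the intended route for production chemistry — any
toolkit's circular fingerprints can be substituted — while the native path
keeps the whole pipeline self-contained and testable.

Desalting keeps the largest covalently connected fragment; equal-size ties
are broken by the lexicographically smallest canonical feature multiset,
which is deterministic and independent of atom numbering.

The circular fingerprint is an iterative Morgan-style expansion: the initial
atom identifier hashes (element, heavy-atom degree, formal charge); each
iteration up to the radius re-hashes an atom's previous identifier together
with its sorted (bond order, neighbor identifier) pairs; the feature set is
the union over iterations.  Radius 2 (the ECFP-4 convention) is the default.
The hash is a seedless 64-bit BLAKE2b digest of canonical tuples, so feature
sets are stable across platforms and sessions.  An atom with no neighbors
keeps its identifier across iterations (its environment cannot grow), so an
isolated atom contributes exactly one feature.  Fingerprints are unfolded by
default; folding modulo `nbits` is available but not used anywhere in the
pipeline, since Tanimoto on unfolded sets is exact.

Duplicate collapsing uses Tanimoto ≥ 1.0 by default — i.e. set-equal
fingerprints — because "duplicate structures" means identity, not analogy.
The threshold is configurable; below 1.0 the grouping is the transitive
closure of the pairwise relation.  The canonical id of a group is its
smallest member id, making dedup idempotent and order-free.

## Target prediction

The reference database is a list of (compound, fingerprint, target set)
records; `n_associations` is the number of (compound, target) pairs.  The
production-scale databases this emulates hold hundreds of thousands of
associations over thousands of proteins; all counts are recomputable from
the record list, so there is no training state beyond counting.

For a query, the k-NN target space is the shortest similarity-ranked prefix
of the database whose annotations cover 10 distinct targets (the whole
database if fewer exist).  Each candidate target is scored with the
Laplacian-corrected naive Bayes log-odds given in the README; features
absent from the database contribute zero, making the score additive over
disjoint feature sets and invariant to junk features.  Ranks are assigned by
descending score, ties broken by descending occurrence then ascending target
id; all other ties (similarity, canonical ids) also fall back to ascending
lexicographic order, so outputs are bit-reproducible.

Precision calibration is leave-one-out by default (k-fold optional with a
seeded assignment): each reference compound is removed from the counts and
the neighbor search, re-predicted, and each prediction marked correct iff
its target is in the held-out compound's annotations.  Predictions
accumulate into bins over occurrence {1, 2, 3, ≥4} × rank {1, 2, 3, 4–10} ×
max Tanimoto {[0, 0.4), [0.4, 0.7), [0.7, 1.0]}.  A cell with fewer than 20
cross-validated predictions falls back to its marginal rank-bin precision,
then to the global precision — coarse, monotone-friendly bins that do not
overfit small reference sets.  Whether the original method's "ranking"
feature orders by score or occurrence, and whether its precision model is
binned or parametric, is not public; binned empirical frequencies over
score-rank were chosen as the simplest faithful reading.

## Target deconvolution

Per screened compound: known targets (reference compounds with an identical
feature set, precision 1.0 by convention) ∪ predictions with precision
strictly above 0.5.  Compounds exceeding 100 targets are dropped as
promiscuous; compounds with no target leave the universe.  The enrichment
universe is all screened, non-promiscuous, target-bearing compounds —
actives and inactives alike; whether the original analysis conditioned on
inactives-with-targets or all screened compounds is ambiguous, and this
choice matches the stated use of both active and inactive compound sets.

Each target is tested with the one-sided hypergeometric upper tail
P(X ≥ k) with N = universe, K = carriers, n = actives, k = active carriers;
zero-count targets are retained at p = 1 so the BH family does not depend on
the draw.  BH adjustment runs within one screen's target family; q < 0.10
declares significance.

## Cross-screen overlap

Only the first screen's labels are shuffled (the second screen's actives
stay fixed), matching the published procedure; shuffling both is available
as an option.  Because a uniform re-assignment of n active labels over N
compounds hits the K B-active shared compounds Hypergeometric(N, K, n)-many
times, the default implementation draws the per-permutation statistic
directly from that distribution — exactly equivalent to, and ~1000× faster
than, materializing each permutation.  A literal label-shuffle path is kept
and cross-checked against the fast path in the tests.  The analytic
hypergeometric tail is always reported next to the empirical p.

When only screen totals are printed, the number of shared compounds active
in the second screen is assigned proportionally:
round(|shared| · |actives_B| / N_B) — an assumption, documented in the
output, overridable with real membership lists.  An empirical p of exactly
zero is rendered as "< 1/n_perm" in text while the numeric field stores 0.

## GO enrichment

Only `is_a` edges are used for propagation (`part_of` is deliberately
ignored, following the stated procedure).  OBO parsing consumes id, name,
namespace and is_a; obsolete terms are dropped; a cyclic is_a graph is an
error naming a cycle member.  Annotation files may be GAF 2.x or a simple
4-column dialect (auto-detected by column count); NOT-qualified rows are
dropped and malformed rows are logged, counted and skipped.  Background ids
without any propagated annotation are excluded from the universe (only
background genes carrying at least one term are counted), configurable.
All terms with K ≥ 1 in the background are tested.  The enrichment kernel is
the same implementation the target deconvolution uses.

## Summary statistics

- Hit rate: 100·k/n rounded half-even to one decimal.
- SEM: sample SD / √n; defined as 0 with a warning at n = 1.
- Two-group comparisons from (mean, SD, n) summaries use the pooled-variance
  Student t-test (not Welch): the source analyses state Student's t, and the
  printed p-values reproduce only under the pooled form.
- One-way ANOVA + Tukey from summaries: MSE pools within-group variances;
  equal-n groups use q = |Δm|/√(MSE/n), unequal n the Tukey–Kramer form;
  adjusted p is the studentized-range upper tail (scipy), accurate to well
  below 1e-4.  At k = 2 the adjusted p equals the pooled t-test p (q =
  |t|·√2).  Published Tukey tables computed from raw data differ from
  summary-based recomputation at the ±0.002 level because printed summaries
  are rounded; tolerances in the tests reflect that.
- ΔΔCt uses the arithmetic mean of reference-gene Cts per condition (the
  log-scale geometric mean of quantities), the standard multi-reference
  normalization; fold = 2^−ΔΔCt.
- Network summaries operate on user-supplied edge lists only (no live
  database queries): average degree 2E/N and mean local clustering with
  degree-<2 nodes counted as 0.
- MeSH bucketing routes tree numbers by prefix into the three D27 branches
  (Molecular Mechanisms D27.505.519, Physiological Effects D27.505.696,
  Therapeutic Uses D27.505.954); a compound counts once per branch touched;
  malformed or non-D27 numbers are tallied unclassified.

## Synthetic data: what it emulates and what it does not

Compounds are random binary feature sets; each reference target owns a
block of 8 features that its annotated compounds carry with probability 0.9
against a 0.02 background rate, so structural similarity is informative
about targets exactly as the predictor assumes.  The dual screen scales the
real screen dimensions ~10× down — 160 and 475 compounds with 108 shared,
baseline hit rates 8.4% and 7.4% — with one planted disease target whose
carriers (~15% of compounds) are active at 0.42, i.e. about 5× baseline, in
both screens; that single mechanism produces both the per-screen target
enrichment and the excess of shared actives.  The ontology generator builds
a depth-3, branching-3 is_a DAG with occasional double parents, annotates
genes to leaves, and over-samples one branch 3× in the study set.

These generators preserve the *statistical* structure the methods exploit,
not chemistry: no molecular property distributions, no dose–response, no
correlated assay noise, no annotation bias.  Passing the recovery tests
shows the inference machinery is correct and calibrated under its own
assumptions; it does not certify performance on real libraries, where
fingerprint similarity is a weaker proxy for shared pharmacology.

At these scaled dimensions the 475-compound screen recovers the planted
target essentially always, while the 160-compound screen does so in roughly
85% of label draws — small screens with ~8% hit rates are genuinely
marginal for single-target recovery at FDR 10%, which is why the power
battery runs on the larger screen.  The planted shared-active excess at
108 shared compounds (~2.7 expected co-actives against a null mean of
~1.7) is likewise detectable only in aggregate, not on every seed; the
published-dimension configuration (32 observed vs 6.7 expected) is the
regime where the permutation test saturates at p < 1e-6.

## Numerical and reproducibility choices

Hypergeometric tails come from `scipy.stats.hypergeom.sf`, BH from
`statsmodels.multipletests(fdr_bh)`, the studentized range from
`scipy.stats.studentized_range`; the tests re-derive each against exhaustive
enumeration or the hand-applied step-up rule.  Every random stage draws from
`default_rng(SeedSequence((seed, stage_code)))`, so toggling one stage never
perturbs another's stream and identical configs rerun byte-for-byte; the
pipeline manifest records a hash of the analytic configuration (paths
excluded) in every table header.  Degenerate inputs are defined rather than
crashed on: empty fingerprint pairs, zero-variance t-tests with equal means
(p = 1, flagged), zero-MSE ANOVA with unequal means (error), k = 0
enrichment rows (p = 1).

## Known limitations

Minimal SMILES (no aromaticity/stereo) means toolkit fingerprints should be
supplied for real libraries; the known-target pass-through matches on exact
fingerprint identity, not substructure; calibration bins are coarse by
design and saturate near precision 1.0 on clean synthetic databases;
the proportional assignment of second-screen actives to the shared set is
an assumption whenever true membership lists are unavailable; and the
two-way ANOVA design used for some published blot quantifications is out of
scope (its replicate structure is ambiguous in the source).
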