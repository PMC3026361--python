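# Methods

## Model

The package treats a gene's literature as a single bag-of-terms document
and a collection of genes as a sparse term-by-document matrix. Two
modeling assumptions carry everything else:

1. **Log-entropy weighting isolates discriminating terms.** The local
   weight log₂(1 + f) compresses raw frequency so term spamming cannot
   dominate; the global weight g = 1 − (normalized Shannon entropy of
   the term's distribution over documents) scales each term by how
   concentrated its usage is. g is invariant to multiplying a term's
   counts by a constant and is 0 exactly for uniform usage, 1 exactly
   for single-document usage. Log base is 2 throughout; any fixed base
   gives the same g and rescales all local weights by one constant.
2. **Nonnegative factors are readable.** A ≈ WH with W, H ≥ 0 expresses
   every document as an additive mixture of k nonnegative term-usage
   patterns. Because cancellation is impossible, a feature's largest
   W-entries are a legible description of a concept, and H[f, g] is a
   direct "how much of concept f is in gene g" strength.

## NMF procedure and numerical choices

- **Updates.** Lee–Seung multiplicative updates on the Frobenius cost
  ½‖A − WH‖²_F. Within one iteration H is updated with the current W,
  then W with the *new* H (the classical interleave); this ordering is
  what makes the per-iteration cost nonincreasing, which the test suite
  asserts with 1e-9 absolute slack. ε = 1e-9 is added to every update
  denominator, so division by zero is impossible and exact zeros in a
  factor stay zero (multiplicative rules cannot resurrect them).
- **Initialization.** NNDSVD: the leading SVD pair enters as
  √σ₁·|u₁|, √σ₁·|v₁| (nonnegative for a nonnegative A by
  Perron–Frobenius); every later pair contributes its sign-consistent
  section with the larger norm product, scaled by √(σ_j μ_j). The SVD is
  computed densely with LAPACK, which is bit-deterministic: two
  initializations of the same matrix agree to 1e-14, so fitted models
  are exactly reproducible. Collections here are desk-scale (≤ a few
  thousand terms × a few hundred documents), so densifying A for the
  one-off SVD is cheap; the iteration itself stays sparse-aware
  (products WᵀA and AHᵀ never densify A).
  The default `mean_fill` variant replaces exact zeros in W0/H0 with the
  mean entry of A, preventing the multiplicative updates from locking
  them; `strict` keeps the zeros for experiments, and a seeded random
  init is available. When the norm product of both sections of a
  singular pair vanishes (possible only on degenerate inputs), that
  component is left zero and `mean_fill` rescues it.
- **Stopping.** The conservative conjunction ‖ΔW‖_F < τ_W = 0.01 AND
  ‖ΔH‖_F < τ_H = 0.001, capped at max_iter = 1000 (both overridable;
  2000 is a reasonable cap for larger collections). `max_iter = 0`
  returns the initialization itself, which is occasionally useful for
  inspecting NNDSVD output.
- **Ranks.** k = 10, 15, 20 are the default low/medium/high resolutions
  for real collections; any 0 < k ≤ min(m, n) is accepted. Low k merges
  themes, high k splits them into more specific concepts.
- **Cost evaluation** uses the expansion ‖A‖² − 2⟨A, WH⟩ + tr((WᵀW)(HHᵀ))
  and clamps tiny negative rounding artifacts at zero.

## Thresholds and tie-breaking

- Gene–feature filters: `global_threshold` (default 1.0 — meaningful
  only on raw, unnormalized log-entropy-scaled H values), `local_percentile`
  (nearest-rank over the gene's own k weights, inclusive ≥, default 70)
  and `relative_max` (H ≥ max H · f_τ). All modes return only strictly
  positive weights, so `relative_max` at f_τ = 0 yields all associated
  genes and at f_τ = 1 exactly the argmax set — monotone shrinking in
  between, which is asserted as a property.
- Correlation windows clamp inward at the feature-range boundary rather
  than wrapping: wrapping would correlate unrelated resolutions. At
  least 3 features are required; zero-variance gene vectors give NaN
  cells flagged as undefined rather than a silent 0.
- All rankings break ties deterministically: weight descending, then
  term lexicographic / feature index / document order.
- Automatic annotation aggregates by *weighted* majority (summed H of
  the passing genes per class), with ties resolved by the single
  heaviest gene and then lexicographically. At f_τ = 1 it reduces to
  labeling each feature by its argmax gene's class. Features with no
  passing genes receive the `unassigned` sentinel; such features
  contribute nothing to multi-label assignment, since the sentinel is
  bookkeeping, not class evidence.
- The new-document classifier applies the model's own weighting to the
  new text (score = Σ log₂(1+f)·g·W[term, ·]) and uses strict (>)
  comparisons for its entropy and frequency thresholds. A document with
  no surviving vocabulary terms yields an all-zero, explicitly flagged
  score vector. Genes whose H column is entirely zero are reported
  `unclassifiable` and counted as errors, not excluded.

## Synthetic corpora

The generator emulates exactly the structure the factorization is meant
to recover: k* topics with pairwise-disjoint signature-term sets;
each document draws every token independently from its topic's
signature pool with probability `signature_fraction`, else from a
shared background pool, both uniformly. Defaults — 5 topics, 30
signature terms per topic, 200 background terms, 20 documents per topic
(or the 26/10/25/37/12 split used for the 110-document study shape),
200 words per document, signature fraction 0.6 — give a collection of
the same scale as a hand-curated review-derived corpus: ~110 documents
over a few-hundred-term dictionary, with enough signature mass that the
topics are identifiable but ~40% background noise.

What this does *not* emulate: Zipfian term frequencies, overlapping or
correlated topic vocabularies, polysemy/synonymy, sentence-level
discourse, or documents of varying length. Passing the end-to-end tests
therefore shows the pipeline recovers planted block structure under
uniform noise — a necessary condition — not that it reaches any
particular accuracy on real literature, where topic overlap and skewed
frequencies make the problem strictly harder. Uniform-within-pool
sampling was chosen over Zipf deliberately: it keeps the expected
entropy weights analyzable and the recovery threshold interpretable;
a Zipfian background is a straightforward extension point.

Determinism contract: the corpus is a pure function of the `TopicSpec`
(including its seed); held-out documents use a seed stream derived from
(seed, topic) that is disjoint from the training stream.

## Design choices where the design was open

- The minimum-frequency rule is applied to the *global* count (total
  over the collection ≥ 2). A per-document reading would remove a term
  from some documents but not others, breaking the single shared
  dictionary that the factorization requires.
- A document that loses all its terms to the filters is an error naming
  the document, since an all-zero column would make its H column
  meaningless rather than merely weak.
- Uniform terms (g = 0) are kept as all-zero rows of A so dictionary row
  indices remain stable across weighting; the updates handle zero rows.
- Sentence splitting is a regex on `[.?!]` + whitespace; sentence
  ranking counts occurrences of the query terms and drops zero-score
  sentences.
- The sklearn estimators (`LogEntropyTransformer`, `LogEntropyNMF`,
  `FaunClassifier`) use the documents-as-samples orientation (X = Aᵀ)
  so they compose with standard pipelines; the functional API keeps the
  terms×documents orientation used everywhere above.

## Problem sizes

The test suite and the acceptance script run on the synthetic study
shape (110 documents, ~350 terms, k = 5, converging in ~30 iterations)
and on random problems up to 300×60 for the factorization properties;
these sizes make every property checkable in seconds while being the
same order as the real collections the method targets.

## Known limitations

- NMF is non-convex; NNDSVD makes the solution reproducible, not
  globally optimal. The truncated-SVD residual is the lower bound the
  tests check against, not an attained value.
- The regularized variants of the cost (sparsity/smoothness penalties on
  W or H) are out of scope, as are alternating-least-squares and
  projected-gradient solvers.
- No gene-name disambiguation: a document collection is taken as given,
  one trusted document per gene.
- The `global_threshold` default of 1.0 presumes raw log-entropy-scaled
  weights; if H is rescaled (the WD·D⁻¹H indeterminacy), only the
  relative and percentile filters remain meaningful.
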