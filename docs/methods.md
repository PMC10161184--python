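# Methods

`semdrift` detects lexical semantic change in year-binned text corpora. The
intended application is large biomedical literature collections (published
papers and preprints) in which both the language and the corpus size change
dramatically over two decades, but nothing in the pipeline is specific to
biomedicine beyond the entity-token convention described below.

## Model and procedure

**Preprocessing.** Documents arrive as year-stamped records, optionally
carrying character-offset entity annotations (concept type and identifier,
as produced by biomedical named-entity taggers). Each annotated span is
collapsed to a single synthetic token `type_id` (e.g. `mesh_d045169`,
`species_694009`, `gene_6301`) so every surface variant of a concept shares
one vector. Versioned documents (preprints) are reduced to their most recent
version before binning to avoid duplication bias. Text is sentence-split and
tokenized by rule; token normalization is a pluggable idempotent `Normalizer`
whose default is Unicode lowercasing. Lemmatization can be supplied as a
normalizer but the package deliberately carries no NLP-runtime dependency.
Sentences — not documents — are the training unit.

**Embedding ensembles.** For each year, R replicate CBOW word2vec models are
trained on the same sentences, differing only in their random seed
(`base_seed + replicate`). Defaults follow the reference analysis: vector
size 300, 10 epochs, minimum count 5, window 16, R = 10. The trainer is an
in-package single-threaded CBOW with negative sampling (5 negatives,
unigram^0.75 noise distribution, subsampling threshold 1e-3, linear learning
rate decay 0.025 → 1e-4), following word2vec.c conventions: the hidden state
is the mean of the context vectors, and the per-position window is shrunk
uniformly at random. Training is bitwise deterministic given the seed; the
internal generator is xorshift64*. Replicates of a year share one vocabulary
by construction.

**Alignment.** Each training run lands in an arbitrary coordinate frame, so
all models are rotated onto a single anchor model (by default replicate 0 of
the latest year) with orthogonal Procrustes: Q = UVᵀ from the SVD of XᵀY,
fit on the vocabulary shared with the anchor, applied to the model's full
vocabulary. No centering, scaling, or translation is applied (both are
exposed as future toggles in the fitting routine's inputs rather than
defaults). Orthogonality guarantees that all within-model cosine distances —
every token's local neighborhood — are preserved exactly; only cross-model
comparisons change.

**Change metric.** For each token and consecutive year pair (y, y+1):

* intra-year distance: mean cosine distance between the token's vectors over
  all R(R−1)/2 replicate pairs within one year (training instability);
* inter-year distance: mean over the R² cross-year model pairs (raw change
  signal);
* frequency ratio f: relative (corpus-size-normalized) frequency in y+1 over
  y. Relative rather than raw frequencies because the corpora grow roughly
  an order of magnitude over the analysis window.

The distance ratio is inter / max(mean(intra_y, intra_{y+1}), 1e-8); the
intra mean over both flanking years uses all available stability
information (a single-year denominator would ignore half of it). The final
metric multiplies the distance ratio by the frequency term. The default
combiner symmetrizes the frequency ratio as max(f, 1/f), so collapses in
usage raise the signal as rises do; the literal directional product
(ratio × f) is a configuration switch. A perfectly stable token (inter =
intra, f = 1) sits at metric 1, and the metric is strictly decreasing in
intra-year instability at fixed inter-year distance — unstable tokens are
penalized, stable ones rewarded. Tokens missing from some years yield gappy
series; no statistic is ever computed across a gap.

**Changepoint calling.** Each token's metric series is scanned with a
two-sided CUSUM over the differences of consecutive timepoints, drift 0:
gp_t = max(0, gp_{t−1} + Δx_t − drift), gn_t analogously with −Δx_t; an
alarm fires when an accumulator exceeds the threshold, both accumulators
reset after an alarm and at series gaps. The threshold defaults to the 99th
percentile (linear interpolation) of all metric values pooled across tokens
and transitions — a single global cutoff, not a per-token one. A call is
localized to the transition at which the alarm fired; no backtracking to
alarm onset is attempted, since at annual resolution the firing transition
is the natural report. One-sided (rise-only) mode is available, as semantic
change is usually framed as a metric increase, but two-sided is the default
because usage collapses are real events. No multiple-testing correction is
applied across tokens.

## Synthetic corpora and what they do (not) show

The generator plants ground truth that real corpora never provide. Background
sentences come from a topic-mixture unigram process identical in every year:
each of V background tokens belongs to one of K topics, a sentence picks a
topic uniformly and draws each token from that topic's members with
probability 0.8 (else from the global vocabulary). Topics give every token a
stable, learnable context distribution — the structure CBOW encodes. A
planted target appears in its own sentences with per-sentence probability
`freq_before` / `freq_after`; its context tokens are drawn from
`context_set_a` before the change year and from the mixture
(1−m)·A + m·B from the change year onward. The mixture weight m is therefore
the effect size of the semantic shift, and the frequency switch is
independently controllable, so the two components of the metric can be
stressed in isolation. Generation is fully deterministic given the seed.

The reference recovery benchmark uses 500 background tokens in 20 topics,
8 years × 20,000 sentences of length 8, one target with a full context shift
(m = 1) at the midpoint year and a 3× frequency rise (0.01 → 0.03 per
sentence). The pipeline configuration for desk-scale benchmarks is dim 50,
3 replicates, 3 epochs, window 16, min count 5: on this corpus 3 epochs is
well past convergence (verified by the intra-year distances, ~0.01), and the
planted transition produces metric spikes two orders of magnitude above the
stable-token baseline. Across 10 generator seeds the planted change year is
recovered within ±1 transition in 10/10 runs with at most ~1% of stable
tokens called. On null corpora (no targets) the pooled exceedance of the
99th-percentile threshold is 1% by construction of the empirical quantile.

What passing these tests does **not** show: the generator produces
exchangeable, topically clean, fixed-length sentences with a single planted
confounder-free shift. Real literature has correlated topic drift, vocabulary
turnover, document-length and section structure, OCR/markup noise, and
simultaneous frequency-and-context confounds; recovery rates here are an
upper bound on real-data behavior, and the synthetic benchmark validates the
machinery, not the biology of any particular corpus.

**Stability diagnostic.** Corpora that grow over time make early-year models
noisier; a single-model year-to-year distance conflates that instability
with genuine change. The diagnostic compares, for tokens present in all
years, the single-model cosine distance to a mid-series reference year
against the integrated statistic (inter-year mean over all replicate pairs,
divided by the mean intra-year distance of the two years). The packaged
diagnostic benchmark uses 6 years with the first two at 2,000
sentences/year and the rest at 20,000, trained deliberately lightly
(1 epoch): the correction addresses run-to-run training noise, so the
diagnostic must sit in the regime where that noise dominates in the small
years — which is where multi-million-token analyses with large vocabularies
actually operate. There the single-model distance is elevated ~two orders
of magnitude in the small-corpus years while the integrated statistic stays
nearly flat. With heavy training on this small synthetic vocabulary the
replicates converge and corpus-sampling noise (which replicates share, since
they see the same sentences) dominates instead; no replicate-based statistic
can correct noise the replicates have in common. This is a known limitation
of the multi-model correction, not of the implementation.

## Numerical and design notes

* Cosine distances are clipped to [0, 2] against floating-point rounding;
  zero-norm vectors are rejected rather than coerced.
* Rotations are computed and applied in float64 and returned in the model's
  storage dtype; rank-deficient cross-covariances are solved anyway (UVᵀ is
  still optimal) but logged as degenerate.
* Vocabulary order is count-descending with lexicographic tie-break;
  neighbor ties break lexicographically; all outputs are deterministically
  ordered.
* The pooled-percentile threshold uses linear interpolation
  (`numpy.percentile` default), and the empirical quantile is inverted the
  same way when a threshold's percentile rank is needed.
* Unknown tokens in frequency lookups return a distinguished missing value
  (`None`), never zero: a zero frequency would fabricate an infinite ratio.
* Ratio points are omitted (not zero-filled) when the earlier year's
  frequency is missing or zero; CUSUM accumulators reset at the resulting
  gaps.
* Overlapping or out-of-range annotation spans reject the document with a
  diagnostic rather than guessing a resolution.
* Model files are word2vec text format written at 9 significant digits, so
  float32 vectors round-trip exactly; token counts and the corpus total ride
  in a TSV sidecar.

## Known limitations

* Single-threaded training: reproducibility is prioritized over wall-clock
  speed; at the reference scale (decades × 10 replicates × millions of
  sentences) training is the dominant cost and would need a parallel trainer
  with documented non-determinism.
* The anchor choice (one replicate of one year) is a convention; multi-set
  Procrustes or iterative anchoring might align better but is out of scope.
* The multi-model correction only addresses replicate-independent noise (see
  the stability diagnostic above).
* The global pooled threshold treats all tokens symmetrically; no frequency
  floor is applied to the pool, and rare-token series are noisier than
  common-token series.
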