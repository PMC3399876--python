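# Methods

This note records the models implemented in `figlink`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions that were
genuinely open.

## Task and data model

An annotated article is an ordered list of abstract sentences, an ordered
list of figures (each a caption plus the body paragraphs that cite it —
tables are treated as figures), and an `n_s × n_f` binary linkage matrix
`L`.  Sentences and figures are numbered 1-based in document order in all
I/O and reports.  Referencing paragraphs are part of the input schema;
detecting citations in running text is out of scope, as is parsing
JATS/HTML/PDF.  Tokenization is a lowercase alphanumeric split with no
stemming; an optional built-in stopword list and minimum token length are
off by default and recorded in the run config, since results depend on
them.  Sentences are represented as sets of words (binary vectors), figure
text as bags of words (counts).

## Language models

Linked sentences are modelled as draws from a two-component mixture: each
term comes from the article background `P_B` with probability λ and from
the figure-specific distribution `P_k` with probability 1−λ; non-linked
sentences are pure background.  The instance score is the resulting
log-odds, summed over the sentence's distinct terms.

Figure-specific distributions are raw frequencies over caption terms,
referencing-paragraph terms, their pool, or the β-mixture of the caption
and referencing distributions.  No pseudo-counts are used: the background
covers terms the figure text lacks.  An empty source falls back to the
other source (logged); if both are empty all mass goes to the background.

Backgrounds pool every token of the article (sentences + captions +
referencing paragraphs).  VariableSize uses add-one smoothing over the
article's own `V_d` distinct terms, with implicit zero probability outside
the pool.  Because a small pool overestimates in-pool probabilities, the
log-odds acquire a negative bias that grows with sentence length;
FixedSize instead smooths with a corpus-level vocabulary size `V ≥ V_d`
(unseen terms get `1/(N+V)`), which empirically removes most of the
length–score correlation (this is asserted as an acceptance property).

Fitting is staged, entirely supervised by mean per-article maximum F1:

* λ: 99-point grid 0.01…0.99, ties broken toward larger λ (more smoothing).
* (λ, β) for mixtures: the 120-point lattice `{(i,j,k) ≥ 0 : i+j+k=14}/14`
  on the 2-simplex, mapped to λ = i/14, β = j/(j+k).  The degenerate
  boundary points (λ = 0 or 1) are kept so the lattice has exactly 120
  points; a per-term odds-ratio floor of 1e-12 keeps the scorer finite
  there.
* `V`: minimizes the absolute Pearson correlation between sentence token
  count and score over training instances, on a geometric grid
  `{V_d·2^i, i ≤ 6} ∪ {5000, 10000, 20000}` above the largest per-article
  `V_d` (the exact smallest-vocabulary grid point reproduces VariableSize
  behaviour for in-pool terms, so the argmin can only reduce the bias).
  FixedSize models first adopt the VariableSize λ (β), pick `V`, then
  re-run the λ (β) search.

A caveat discovered during development and verified by a
true-distribution control: the max-F1 objective is a pure ranking
criterion, and with unsmoothed figure models any sentence term absent from
the figure text contributes `log λ`, so rankings improve monotonically in
λ and the grid argmax sits near 0.99 regardless of the λ that generated
the data.  Scoring with the *true* generating distributions (full support)
makes the objective peak near the generating λ.  Fitted λ should therefore
be read as a smoothing setting tuned for ranking, not as an estimate of
the generative background fraction; the acceptance suite states the
recovery property at face value and it fails honestly.

The TFIDF baseline scores cosine similarity between TFIDF vectors of the
sentence and the figure's pooled text, with article-level smoothed IDF
`ln((1+n)/(1+df)) + 1` over the article's sentence+figure documents (raw
`log(n/df)` would zero out terms shared by all documents, making identical
texts score 0 rather than 1).  Whether the historical baseline used
corpus- or article-level IDF is unknown; this implementation is documented
as approximate.

## Distance model

The Distance feature is `j/n_s − k/n_f` (the relative-position
difference; the normalization is a config option).  Ten equal-frequency
bins are cut at the deciles of all training distances — all instances
pooled, not per class — with left-closed right-open bins, the last bin
closed, and prediction-time clamping to the end bins.  Linked and
non-linked bin distributions are Laplace smoothed (`+1` per bin); the
score is the bin log-odds.  `Z = S + D` is exact under conditional
independence of terms and positions given linkage.

## Sequence models

**HMM.**  Under SIS, states are `q_0` (non-linked) plus one per sentence;
the observation sequence is the article's figures in order.  The base
transition matrix over `M_max+1` states (the largest training article) is
estimated by co-occurrence counting — for each consecutive figure pair,
every (sentence linked at k−1, sentence linked at k) pair increments a
count, with `q_0` standing in for link-less figures — followed by a
Dirichlet(1) MAP.  Multi-linked figures therefore contribute all pairs;
no arbitrary single sentence is selected.  Per-article models restrict the
base matrix to the article's states and renormalize rows; larger articles
get extra states carrying the prior mass `1/(M_max+1)` before
renormalization.  The start distribution (not specified by the original
construction) is a Dirichlet-1 MAP over first-step linkage, with a uniform
option.  Emissions calibrate instance scores with two Gaussians (linked /
non-linked moments, unbiased variance, σ floored at 1e-6 with a warning);
a step's emission vector is the normalized joint density of its score
column under each state's implied linkage, so `b_i/b_0` is the per-entity
density ratio.  Scores default to `Z` (LM+DM); whether the original final
models used `S` or `Z` is unclear, so it is a config switch.  Posterior
decoding uses scaled forward–backward (no underflow at realistic lengths);
Viterbi is deliberately absent.

**CRF.**  States are sentence subsets of size ≤ `D_max` (default 2; state
count `Σ_{d≤D_max} C(n_s,d)`), enumerated by size then lexicographically.
Transition affinities are `exp(w·f)` over eight shared features:
destination-degree one-hot (0/1/2/3+; the 3+ feature cannot fire at
`D_max` = 2 but is retained for larger configurations), implied crossed
edges `|{(i,i'): i ∈ dest, i' ∈ source, i' > i}|`, `|source ∩ dest|`,
within-destination adjacent sentences (destination only, preventing double
counting across consecutive transitions), and the diagonal pattern
`|{i ∈ dest: i−1 ∈ source}|`.  Start affinities use the same features with
an empty source.  Emission affinities are the HMM construction generalized
to subsets.  Training maximizes the conditional log-likelihood of gold
paths (figures linking more than `D_max` sentences keep the lowest-indexed
ones; truncations are counted and logged) by deterministic batch gradient
ascent with backtracking line search, starting from zero weights;
gradients are observed-minus-expected feature counts via forward–backward
in log space.  An L2 penalty (default 1e-2, not part of the original
formulation) stabilizes training; set it to 0 to match the unregularized
objective.  Convergence: gradient infinity-norm < 1e-4 or 200 iterations.
Prediction sums per-step state posteriors over states containing each
sentence.  FIS mirrors SIS with roles swapped (one code path).

## Evaluation

Precision, recall, FPR and F1 = 2RP/(R+P) follow the standard confusion
conventions (precision of an empty positive set is 0 with a warning).
Curves sweep thresholds over distinct score values with ties grouped, and
AROC is the trapezoid area — identically 0.5 for label-independent
constant scores.  Two aggregation schemes are reported: whole-corpus
(pool, then compute) and per-article (compute, then average); per-article
AROC skips single-class articles, and articles with no gold links
contribute max-F1 = 0 (an exclusion option exists).  Whole-corpus max-F1
is *expected* below the per-article mean for model scores (the pooled
scheme shares one threshold), but this is not a theorem for arbitrary
matrices — a well-separated article plus a badly-ranked one can invert
it — so the suite asserts it only for model-evaluated corpora.
Precision-at-reference predicts the top `n_s` instances per article (or
`Σ n_s` pooled) with deterministic (article, j, k) tie order.  Clicks
saved: per sentence, the document position of its last linked figure minus
the smallest ranked prefix covering all its linked figures, averaged over
all sentences.  The article-effect permutation test reassigns instances to
articles preserving each article's instance and linked counts (linked and
non-linked pools shuffled separately, one seeded generator, default 1000
permutations).  Leave-one-article-out cross-validation refits every
learnable parameter per fold; held-out scoring uses only the article's own
text, so no linkage leaks.

## Synthetic corpora

The generator emulates: per-sentence and per-figure link-degree
distributions (the published marginals P(0), P(1) for both sides, with
the ≥2 mass truncated at 3 and split to match the published mean degrees
of 1.146 links/sentence and 1.278 links/figure — which also balances the
two sides' expected totals); order-preserving links (the sampled degree
sequences are realized by their unique non-crossing monotone alignment;
with preservation strength < 1, a (1−strength) fraction of links get
randomly swapped endpoints, and degree draws whose forced alignment would
duplicate a pair are repaired by degree-preserving endpoint swaps);
and the LM's generative story (background and per-figure topic term
distributions are symmetric Dirichlets over a shared vocabulary; captions
and referencing paragraphs are topic draws; linked sentences mix
background and linked-topic tokens at the configured background fraction
λ*; unlinked sentences are pure background).  Degree draws are rejected
until sentence and figure totals match (capped, then an error).

Defaults: 30 articles, 5–10 sentences, 4–9 figures, vocabulary 500,
background Dirichlet 0.5, topic Dirichlet 0.05, λ* = 0.7, caption 40
tokens, 2 referencing paragraphs of 60 tokens, Poisson(12) sentence
lengths (min 4), order preservation 0.9.  These sizes track the published
corpus averages (≈7 sentences, ≈6.5 figures per article, ≈16–17% linked
instances); the text parameters were chosen so that a fitted LM is
clearly but not perfectly informative.  What the generator does *not*
emulate: Zipfian word frequencies, function words, multi-topic figures,
section structure, or any linguistic realism — so passing tests show the
estimators and decoders behave as designed under their own modelling
assumptions, not that the accuracies transfer to real articles.

The model-ordering acceptance check (CRF ≥ HMM ≥ LM+DM ≥ LM ≥ DM in mean
per-article max-F1) runs under *strong-flow / weak-text* conditions:
order preservation 1.0, λ* = 0.885, topic Dirichlet 0.02, 36 articles per
seed (24 train / 12 test), 40 seeds, sign test per adjacent pair.  Strong
flow makes the collective models' transition signal matter; the text is
kept sparse (≈1 topical token per 9) but sharp so the LM still beats the
distance-only model.  These are the conditions under which the ordering
is claimed; with strong text the LM+DM ceiling leaves the sequence models
little headroom, and with no text all models collapse toward the
distance model.

## Numerical choices and degenerate inputs

Probability computations for the sequence models run in log space
(hand-rolled log-sum-exp on the hot path); forward–backward uses per-step
scaling (HMM) or log messages (CRF).  Tie-breaks are deterministic
everywhere: λ ties toward more smoothing, `V` ties toward the smaller
vocabulary, top-n selections by (article, j, k), ranking ties by document
order.  Equal-frequency binning for information gain uses average ranks,
so the % gain is invariant to strictly monotone transforms; features with
≤ n_bins distinct values are used as-is.  Undefined neighbour features at
article borders are explicit missing values; consumers declare a fill
policy (default 0).  Degenerate cases: empty term pools, single-class
gold vectors, zero-variance Gaussian classes, infeasible degree draws and
non-finite CRF objectives all raise or warn explicitly rather than
returning silent zeros.

## Known limitations

* Scores are comparable within an article, not across articles (the
  permutation test exists precisely to quantify this article effect);
  a single global threshold is inappropriate.
* Fitted λ/β/V are ranking-tuned, not generative estimates (see above).
* The CRF's `D_max` truncation discards links of figures with more than
  `D_max` sentences during training (rare at the default degree
  distributions, but counted and logged).
* The TFIDF baseline is an approximation; treat baseline comparisons as
  indicative only.
* Runtime scales with `Σ_{d ≤ D_max} C(n_s, d)` squared per CRF step;
  `D_max > 3` on long abstracts gets expensive.
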