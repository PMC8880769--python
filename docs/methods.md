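# Methods

## The model

`cuedchoice` treats open-ended sequential choice — most concretely, an
online grocery shopper deciding what to add to the basket next — as cued
retrieval from long-term memory. The item just chosen acts as a probe;
candidate items are retrieved according to their associative strength
with that probe, aggregated over several knowledge sources. Given the
cue `x_t` and the set `R_t` of catalog items not yet chosen this trip,
the probability of choosing `j` next is the Luce form used in
search-of-associative-memory models:

    P(j | x_t) ∝ ∏_k (S_k(x_t, j) + ε)^{β_k},   j ∈ R_t

with one similarity matrix `S_k ∈ [0,1]^{n×n}` per knowledge source and
one non-negative attention weight `β_k` per source and shopper. The
smoothing constant ε (default 1e-6) keeps zero similarities from
annihilating the product; all computation happens in the log domain.
A softmax-of-linear-combination variant (`rule="linear"`) is available
for sensitivity analyses. The first item of a trip has no cue and is
excluded from the likelihood; retrieval is without replacement, so the
choice set shrinks by one each step.

Three knowledge sources are represented:

* **Episodic** — `S(i,j) = n_ij / N`, the probability that products
  `i` and `j` co-occur in the same unordered basket, over `N` baskets.
  A symmetric joint probability is used rather than the conditional
  `n_ij / n_i` (available via `conditional=True`) because the choice
  rule expects a symmetric score.
* **Semantic** — cosine similarity between distributed product
  embeddings trained on within-basket co-occurrence, with negative
  cosines clamped to 0 so entries stay in `[0,1]`. The default trainer
  is PPMI + truncated SVD, which is exactly reproducible; a seeded
  skip-gram-with-negative-sampling trainer (`method="sgns"`) is the
  word2vec-style alternative. Embedding vectors are mean-centred before
  the cosine (common-component removal): PPMI factorisations give every
  product a large shared positive component that inflates all cosines
  and mostly encodes raw frequency, and removing it leaves the
  directions that discriminate between product meanings. Without this
  step the semantic matrix is close to a blurred copy of the episodic
  one and the semantic attention weight is poorly identified.
* **Hierarchical** — the fraction of shared levels on two products'
  root-to-leaf paths in a depth-`D` (default 5) product taxonomy,
  counted from the top down to the first divergence. It takes values in
  `{0, 1/D, …, 1}` and equals 1 iff two products share a leaf.

## Fitting and model comparison

Each shopper is fit independently by maximum likelihood over
`β ∈ [0, 50]^k` with L-BFGS-B and analytic gradients. The negative log
likelihood of the product rule is convex in β (linear scores minus a
log-sum-exp), so the optimum is global; the default 5 seeded restarts
are a safety net, with ties resolved to the lowest restart index.
Candidate models are the 7 non-empty subsets of
{episodic, semantic, hierarchy}. Each fit reports
`BIC = k·ln(n_transitions) − 2·logL` and the percentage improvement
over the zero-parameter random baseline (uniform over remaining
products, whose likelihood has the closed form `∏_t 1/(M−t)`):

    ΔBIC% = 100 · (BIC_random − BIC_model) / BIC_random.

This form is scale-free and positive exactly when the model beats the
baseline. Population summaries report means with normal-theory 95% CIs
across shoppers.

Identifiability is checked by simulate-and-refit parameter recovery:
draw per-shopper true weights, sample trips from the model, refit, and
report the Pearson correlation between true and estimated values per
parameter. A parameter with zero variance across shoppers is reported
as NaN rather than a correlation.

## Synthetic data

The generator provides ground truth for every pipeline stage and plants
exactly the structures the analyses are meant to detect.

* **Taxonomy** — a random tree with configurable per-level branching
  (default `(3,3,3,3,3)`, 243 leaves); products are spread round-robin
  over a random permutation of leaves.
* **Baskets** — built from latent **themes** and **recipes**. Themes are
  small sets of substitutable products (default size 5) carved out of
  taxonomy branches, with a `cross_category_rate` fraction (default 0.5)
  of products swapped between themes so that neither co-occurrence nor
  embedding structure collapses onto the taxonomy. Recipes are
  combinations of complementary themes; each basket samples 1–2 goals
  (recipe instantiations picking one product per theme) plus ~10%
  uniform noise products. Substitutes thereby share contexts without
  co-occurring (semantic signal) while complements co-occur directly
  (episodic signal) — the separation that makes the three attention
  weights jointly identifiable.
* **Trips** — the first item is uniform over the catalog; subsequent
  items are sampled from the retrieval rule itself with known
  per-shopper weights drawn uniformly from episodic `[0, 0.5]`,
  semantic `[0, 0.2]`, hierarchy `[0, 4]` — ranges spanning the regime
  estimated on real shoppers, with hierarchy dominant and semantic
  smallest.
* **Response times** — `IRI_t = a − Σ_k b_k·S_k(prev, cur) + c·t +
  N(0, σ)` (defaults a = 30 s, b = 8 s per unit similarity, c = 0.15 s
  per timestep, σ = 2 s): similar successors are faster, trips slow
  down late.
* **Navigation labels** — drawn i.i.d. with shares proportional to the
  mean per-trip usage of search bar, category menu, special offers, and
  the pre-checkout reminder reported for large online grocery panels
  (≈ 83 / 11 / 5 / 1%).
* **Error counts** — per-shopper forgotten (retrieval misses, bought
  from the pre-checkout reminder) and removed (false alarms) counts are
  Poisson with log-mean linear in the standardised true weights;
  default signs make episodic and hierarchical reliance protective and
  semantic reliance harmful for both error types.
* **Trip lengths** — a fixed count or a uniform integer range;
  simulations here default to 30 choices per trip, within the small-to-
  medium range of real visits.

All randomness flows through `numpy.random.default_rng`; stage seeds
are derived from the single configuration seed, so a fixed seed gives
byte-identical corpora and trips.

What the generator does **not** emulate: goal satisfaction and checkout
timing, website layout and recommender ranking, basket-size/price
covariation, shopper-level heterogeneity in navigation preferences, and
any text or image content. Passing tests therefore show that the
estimator and analyses recover what the model plants, not that real
shoppers satisfy the model.

## Sequence analyses

* **Permutation test** — per trip, mean similarity of consecutive
  purchases for the true order versus random within-trip permutations
  (default 1 shuffle per trip, configurable); two-sided Mann-Whitney U
  on the two samples of trip means, effect size `CLE = U/(n1·n2)`.
* **Lag profile** — per shopper, mean similarity between each choice
  and the item `ℓ` steps back for `ℓ = 1..10`, z-scored within shopper
  across lag means, OLS slope on the lag value (−10..−1). Population:
  mean slope with 95% CI and a two-sided exact binomial sign test on
  slope signs (normal-approximation Z reported). Shoppers with fewer
  than 3 choices are excluded; short trips contribute the lags they
  have. With heavily skewed similarities and very short trips the
  extreme-lag means rest on few pairs and the z-scored slope acquires a
  small positive bias; null calibration holds for trips long enough to
  populate the lag window (≳ 3× the maximum lag).
* **Timestep regression** — transitions binned into deciles of relative
  within-trip position (equal-width bins on the 0–1 relative timestep,
  which weights trips equally), standardised similarity regressed on
  decile index with navigation-method indicators as confounds.
* **IRI regression** — standardised OLS of the inter-response interval
  on the three similarities plus configurable covariates (timestep and
  products-remaining by default) and navigation indicators.
  Non-positive or missing IRIs are dropped with a logged count. With
  fixed trip lengths products-remaining is perfectly collinear with
  timestep; the covariate list is configurable for that reason.
* **Error analysis** — Spearman correlations (Fisher-z 95% CIs) between
  each fitted attention weight and the forgotten/removed counts, plus a
  multiple regression of each count on scaled weights with the number
  of choices and per-shopper navigation shares as confounds.

Every analysis accepts a navigation-method filter that restricts trips
to choices made through the given methods (e.g. search-bar only),
renumbers the surviving subsequence, and runs the identical code path —
the robustness check for interface-induced transitions.

## Transition clustering

Consecutive choices are mapped to taxonomy groups at a caller-chosen
level (the level is a required argument; intuitive higher-order blocks
appear at intermediate levels). Lift is the joint transition frequency
over the product of source and destination marginals; groups with zero
marginals get undefined (NaN) lift. The clustering affinity is the
symmetrised positive part of lift−1 (negative excess carries no
enrichment evidence), embedded with the top eigenvectors of the
normalised affinity and partitioned by seeded k-means; the number of
clusters is chosen by maximum silhouette on the embedding, ties to the
smaller k. A disconnected affinity triggers a warning and the
components dominate the resulting partition.

## Numerical choices and degenerate inputs

* ε = 1e-6 smoothing in the choice rule; likelihoods and probabilities
  via log-sum-exp throughout.
* β bounds [0, 50]; estimates exactly at 0 are legitimate (boundary
  censoring slightly attenuates recovery correlations for weights near
  zero).
* Constant similarity vectors: permutation test returns CLE 0.5 and
  p = 1; lag slopes are 0; Spearman correlations on constant inputs are
  reported NaN.
* All-identical similarity matrices make recovery unidentifiable and
  raise a warning.
* SVD sign ambiguity is fixed by orienting each singular vector to make
  its largest-magnitude entry positive, so embeddings are reproducible.

## Problem sizes

The shipped simulations use a 300-product catalog, 2,000 baskets, 300
shoppers, and 30-item trips for the recovery study, and ~100-product
catalogs with 40–500 shoppers for the analysis validations. These sizes
put every planted effect several standard errors from its null while
keeping a full test run in the minutes range; all of them scale up by
configuration.

## Known limitations

* The semantic and episodic channels both derive from the basket
  corpus; their identifiability rests on the theme/recipe separation
  the generator plants and on mean-centred embeddings. With embeddings
  trained on text or with denser corpora the cross-channel correlation,
  and hence recovery quality, will differ.
* Per-shopper fits assume one pooled sequence per shopper and at least
  one trip of length ≥ 2; trips are modelled as exchangeable given β.
* The IRI model is linear-Gaussian; real response times are
  right-skewed, so the regression recovers signs and standardised
  magnitudes, not a process model of latencies.
* Goal acceptance/rejection is outside the model: the likelihood
  describes retrieval order, not why an item was wanted.
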