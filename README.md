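# cuedchoice

Multi-cued memory retrieval models of open-ended sequential choice.

When people choose from an enormous set of options one item at a time —
adding groceries to an online basket, naming animals in a fluency task —
each choice tends to cue the next. `cuedchoice` implements a
computational account of this process: the previous choice probes
long-term memory, and candidates are retrieved in proportion to their
attention-weighted associative strength across several knowledge
sources. The package is aimed at computational cognitive scientists and
quantitative researchers who want to fit retrieval models to sequential
choice logs, or to study the identifiability of such models on
synthetic data with known ground truth.

## The model

Given the previous choice `x_t` and the set `R_t` of not-yet-chosen
catalog items, the next choice follows the Luce retrieval rule used in
search-of-associative-memory models:

    P(j | x_t) = ∏_k (S_k(x_t, j) + ε)^{β_k} / Σ_{j'∈R_t} ∏_k (S_k(x_t, j') + ε)^{β_k}

with one similarity matrix per knowledge source and one non-negative
attention weight β_k per source and shopper:

* **episodic** `S(i,j)` — probability that `i` and `j` co-occur in the
  same unordered shopping basket;
* **semantic** — clamped cosine similarity of product embeddings
  trained on basket co-occurrence (PPMI+SVD or skip-gram);
* **hierarchy** — fraction of shared levels on the two products'
  root-to-leaf paths in a five-level product taxonomy.

Shoppers are fit independently by maximum likelihood; the seven
non-empty subsets of knowledge sources are compared by BIC against a
uniform-over-remaining-products baseline (reported as ΔBIC%, the
percentage BIC improvement). On top of the model sit the standard
sequence analyses — permuted-order similarity tests with common-language
effect sizes, lag ("ripple") profiles, similarity-by-timestep and
response-time regressions, error analyses linking attention weights to
forgotten/removed items — and lift-based spectral clustering of
transitions between taxonomy groups. A synthetic-data module generates
taxonomies, goal-structured basket corpora, and trips sampled from the
retrieval rule itself, so every stage can be validated against planted
ground truth. See `docs/methods.md` for details.

## Worked example

Simulate a small shopper population with known attention weights, build
the three representations from the simulated baskets, and compare all
candidate models:

```python
import cuedchoice as cc
from cuedchoice import analyses

cfg = cc.SimulationConfig(catalog_size=120, n_baskets=1000, n_shoppers=80,
                          trip_length=(20, 35), seed=7)
sim = cc.simulate(cfg)

per_fit, summary = cc.compare_models(sim.trips, sim.store, seed=7)
print(summary[["model_spec", "delta_bic_pct_mean"]].round(2).to_string(index=False))

res = analyses.permutation_similarity_test(sim.trips, sim.store, "hierarchy", seed=7)
print(f"CLE={res.cle:.3f}, median_true={res.median_true:.3f}, "
      f"median_permuted={res.median_permuted:.3f}")
```

Output:

```
                 model_spec  delta_bic_pct_mean
         semantic+hierarchy               43.06
episodic+semantic+hierarchy               42.94
         episodic+hierarchy               40.45
                  hierarchy               39.80
                   semantic                3.56
          episodic+semantic                2.70
                   episodic               -0.26
CLE=0.866, median_true=0.470, median_permuted=0.296
```

Reading the numbers: hierarchy-containing models explain simulated
choices far better than the random baseline (ΔBIC% ≈ 40), matching the
hierarchy-dominant weights the population was generated with (mean true
β: episodic 0.23, semantic 0.11, hierarchy 2.10); the full model and
the semantic+hierarchy model are statistically tied here because many
simulated shoppers drew small episodic weights, so the extra parameter
does not always pay its BIC penalty at n = 80. The permutation test
shows consecutive choices are far more similar than randomly permuted
orders (CLE 0.87: an 87% chance a random true-order trip beats a
permuted one). The mean fitted weights of the full model
(0.27 / 0.11 / 2.16) track the generating means.

The same workflow is available from the shell:

```sh
cuedchoice simulate --seed 7 --out results/sim
cuedchoice fit --trips results/sim/trips.csv --store results/sim/store \
    --models all --out results/fits.csv
cuedchoice analyze --trips results/sim/trips.csv --store results/sim/store \
    --which permutation,lag,iri --out results/analyses
cuedchoice cluster --trips results/sim/trips.csv \
    --taxonomy results/sim/taxonomy.csv --level 4 --out results/clusters.csv
```

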