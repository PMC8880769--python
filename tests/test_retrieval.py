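"""Tests of the retrieval likelihood: brute-force oracle equivalence,
closed-form baselines, fitting determinism, and BIC bookkeeping."""

import math

import numpy as np
import pytest

import cuedchoice as cc
from cuedchoice.retrieval import MODEL_SPECS, _random_baseline_loglik

from conftest import make_trips


def brute_force_probabilities(cue, remaining, store, beta, epsilon):
    """Literal term-by-term evaluation of the retrieval equation."""
    weights = {}
    for j in remaining:
        w = 1.0
        for name, b in beta.items():
            w *= (store.similarity(name, cue, j) + epsilon) ** b
        weights[j] = w
    Z = sum(weights.values())
    return {j: w / Z for j, w in weights.items()}


class TestChoiceProbabilities:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, toy_store, seed):
        rng = np.random.default_rng(seed)
        beta = {
            "episodic": float(rng.uniform(0, 3)),
            "semantic": float(rng.uniform(0, 3)),
            "hierarchy": float(rng.uniform(0, 3)),
        }
        cue = "A"
        remaining = ["B", "C", "D"]
        p = cc.choice_probabilities(cue, remaining, toy_store, beta)
        expected = brute_force_probabilities(cue, remaining, toy_store, beta, 1e-6)
        for j in remaining:
            assert abs(p[j] - expected[j]) < 1e-10

    def test_matches_brute_force_on_larger_catalog(self, small_sim):
        catalog = small_sim.store.catalog[:20]
        sub = cc.SimilarityStore(
            catalog=catalog,
            matrices={
                k: m[:20, :20] for k, m in small_sim.store.matrices.items()
            },
        )
        beta = {"episodic": 0.3, "semantic": 0.15, "hierarchy": 2.0}
        p = cc.choice_probabilities(catalog[0], catalog[1:], sub, beta)
        expected = brute_force_probabilities(catalog[0], catalog[1:], sub, beta, 1e-6)
        assert max(abs(p[j] - expected[j]) for j in catalog[1:]) < 1e-10

    def test_zero_betas_uniform(self, toy_store):
        p = cc.choice_probabilities(
            "A", ["B", "C", "D"], toy_store, {"episodic": 0.0, "hierarchy": 0.0}
        )
        for v in p.values():
            assert v == pytest.approx(1 / 3)

    def test_single_representation_ratio(self):
        # one representation, beta=1, eps -> 0, S(cue, .) = (0.2, 0.1):
        # probabilities are 2/3 and 1/3
        S = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.0], [0.1, 0.0, 1.0]])
        store = cc.SimilarityStore(catalog=("c", "x", "y"), matrices={"episodic": S})
        p = cc.choice_probabilities(
            "c", ["x", "y"], store, {"episodic": 1.0}, epsilon=1e-12
        )
        assert p["x"] == pytest.approx(2 / 3, abs=1e-9)
        assert p["y"] == pytest.approx(1 / 3, abs=1e-9)

    def test_normalisation(self, toy_store):
        p = cc.choice_probabilities(
            "B", ["A", "C", "D"], toy_store, {"episodic": 5.0, "hierarchy": 0.7}
        )
        assert abs(sum(p.values()) - 1.0) < 1e-12

    def test_monotonicity_in_attention_weight(self, toy_store):
        # A dominates C on hierarchy from cue B (0.8 vs 0.4) and ties are
        # irrelevant with other weights at 0: raising beta_hierarchy must
        # strictly raise P(A)
        last = 0.0
        for b in (0.5, 1.0, 2.0, 4.0):
            p = cc.choice_probabilities("B", ["A", "C"], toy_store, {"hierarchy": b})
            assert p["A"] > last
            last = p["A"]

    def test_error_conditions(self, toy_store):
        with pytest.raises(cc.InvalidConfigError):
            cc.choice_probabilities("A", [], toy_store, {"episodic": 1.0})
        with pytest.raises(cc.InvalidConfigError):
            cc.choice_probabilities("A", ["A", "B"], toy_store, {"episodic": 1.0})
        with pytest.raises(cc.InvalidConfigError):
            cc.AttentionWeights(beta={"episodic": -0.1})


class TestSequenceLogLikelihood:
    def test_uniform_closed_form(self, toy_store):
        # all beta = 0: logL = sum_t log(1/(M - t))
        trip = ["A", "B", "C"]
        ll = cc.sequence_log_likelihood(trip, toy_store, {"episodic": 0.0})
        assert ll == pytest.approx(math.log(1 / 3) + math.log(1 / 2))
        assert ll == pytest.approx(_random_baseline_loglik([trip], 4))

    def test_single_transition_matches_probability(self):
        S = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.0], [0.1, 0.0, 1.0]])
        store = cc.SimilarityStore(catalog=("c", "x", "y"), matrices={"episodic": S})
        ll = cc.sequence_log_likelihood(
            ["c", "x"], store, {"episodic": 1.0}, epsilon=1e-12
        )
        assert ll == pytest.approx(math.log(2 / 3), abs=1e-9)

    def test_nonpositive(self, toy_store):
        ll = cc.sequence_log_likelihood(
            ["D", "A", "C"], toy_store, {"hierarchy": 3.0, "semantic": 0.2}
        )
        assert ll <= 0

    def test_repeated_product_rejected(self, toy_store):
        with pytest.raises(cc.InvalidConfigError):
            cc.sequence_log_likelihood(["A", "B", "A"], toy_store, {"episodic": 1.0})

    def test_generating_weights_beat_perturbed_on_average(self, small_sim):
        # self-consistency: the likelihood of the generating weights
        # exceeds that of perturbed weights, averaged over replicates
        true = {"episodic": 0.3, "semantic": 0.1, "hierarchy": 2.0}
        perturbed = {"episodic": 1.5, "semantic": 0.8, "hierarchy": 0.2}
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.0], n_shoppers=40, trip_length=20, seed=21
        )
        diffs = [
            cc.sequence_log_likelihood(seq, small_sim.store, true)
            - cc.sequence_log_likelihood(seq, small_sim.store, perturbed)
            for seq in trips.sequences().values()
        ]
        assert np.mean(diffs) > 0


class TestFitting:
    def test_bic_identity_and_determinism(self, small_sim):
        seq = list(small_sim.trips.sequences().values())[0]
        f1 = cc.fit_shopper([seq], small_sim.store, seed=5)
        f2 = cc.fit_shopper([seq], small_sim.store, seed=5)
        k, n = len(f1.model_spec), f1.n_transitions
        assert f1.bic == pytest.approx(k * math.log(n) - 2 * f1.log_likelihood)
        assert f1.beta_hat.beta == f2.beta_hat.beta

    def test_null_data_fits_near_zero_with_bic_penalty(self, small_sim, null_trips):
        seqs = list(null_trips.sequences().values())[:25]
        fits = [
            cc.fit_shopper([s], small_sim.store, ("hierarchy",)) for s in seqs
        ]
        betas = [f.beta_hat.beta["hierarchy"] for f in fits]
        assert np.median(betas) < 0.3
        # with no signal the k>=1 model only pays the BIC penalty
        assert np.mean([f.delta_bic_pct for f in fits]) < 0

    def test_single_representation_generator_wins_model_selection(self, small_sim):
        # data from a hierarchy-only model: the 1-parameter hierarchy
        # model should post the best mean BIC among all 7 subsets
        trips, _ = make_trips(
            small_sim.store, [0.0, 0.0, 3.0], n_shoppers=12, trip_length=20, seed=31
        )
        per_fit, _ = cc.compare_models(trips, small_sim.store, n_restarts=2)
        mean_bic = per_fit.groupby("model_spec")["bic"].mean()
        assert mean_bic.idxmin() == "hierarchy"

    def test_two_item_trip_boundary(self, toy_store):
        trips = cc.TripLog(
            trips=__import__("pandas").DataFrame(
                {
                    "shopper_id": ["s", "s"],
                    "timestep": [1, 2],
                    "product_id": ["A", "B"],
                    "iri_seconds": [np.nan, 3.0],
                    "nav_method": ["search", "search"],
                }
            )
        )
        per_fit, summary = cc.compare_models(trips, toy_store, n_restarts=2)
        assert (per_fit["n_transitions"] == 1).all()
        assert len(per_fit) == len(MODEL_SPECS)

    def test_recovery_reports_nan_for_constant_truth(self, small_sim):
        cfg = cc.SimulationConfig(
            catalog_size=100,
            n_shoppers=8,
            trip_length=10,
            true_betas=np.tile([0.2, 0.1, 1.0], (8, 1)),
            seed=3,
        )
        report = cc.parameter_recovery(cfg, store=small_sim.store, n_restarts=2)
        assert all(math.isnan(v) for v in report.pearson_r.values())

    def test_degenerate_store_warns(self):
        S = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        store = cc.SimilarityStore(
            catalog=("a", "b", "c"),
            matrices={"episodic": S, "semantic": S, "hierarchy": S},
        )
        cfg = cc.SimulationConfig(
            catalog_size=3, n_shoppers=4, trip_length=3, seed=1
        )
        with pytest.warns(UserWarning, match="identical"):
            cc.parameter_recovery(cfg, store=store, n_restarts=1)
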