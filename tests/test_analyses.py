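"""Tests of the sequence analyses: permutation test, lag ripple, timestep
and IRI regressions, and the attention-weight error analysis. Regression
outputs are checked against a hand-rolled normal-equations solver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cuedchoice as cc
from cuedchoice import analyses

from conftest import make_trips


def brute_force_cle(x, y):
    """Pairwise win count (ties half) divided by n1*n2."""
    wins = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y
    )
    return wins / (len(x) * len(y))


class TestPermutationTest:
    def test_cle_equals_brute_force_pair_count(self, small_sim):
        res = analyses.permutation_similarity_test(
            small_sim.trips, small_sim.store, "episodic", seed=4
        )
        # recompute both samples exactly as the test does
        rng = np.random.default_rng(4)
        sim = small_sim.store.matrices["episodic"]
        true, perm = [], []
        for seq in small_sim.trips.sequences().values():
            idx = small_sim.store.indices(seq)
            true.append(sim[idx[:-1], idx[1:]].mean())
            p = rng.permutation(idx)
            perm.append(sim[p[:-1], p[1:]].mean())
        assert res.cle == pytest.approx(brute_force_cle(true, perm), abs=1e-12)

    def test_null_trips_show_no_effect(self, small_sim, null_trips):
        res = analyses.permutation_similarity_test(
            null_trips, small_sim.store, "hierarchy", seed=9
        )
        assert 0.42 <= res.cle <= 0.58

    def test_hierarchy_driven_trips_detected(self, small_sim, hier_trips):
        res = analyses.permutation_similarity_test(
            hier_trips, small_sim.store, "hierarchy", seed=10
        )
        assert res.cle > 0.5
        assert res.median_true > res.median_permuted
        assert res.p_value < 0.01

    def test_length_two_trip_permutation_is_symmetric(self, toy_store):
        trips = cc.TripLog(
            trips=pd.DataFrame(
                {
                    "shopper_id": ["s"] * 2,
                    "timestep": [1, 2],
                    "product_id": ["A", "D"],
                    "iri_seconds": [np.nan, 2.0],
                    "nav_method": ["search"] * 2,
                }
            )
        )
        res = analyses.permutation_similarity_test(trips, toy_store, "episodic")
        assert res.median_true == pytest.approx(res.median_permuted)
        assert res.cle == pytest.approx(0.5)

    def test_constant_similarity_degenerate_path(self):
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        store = cc.SimilarityStore(catalog=("a", "b", "c"), matrices={"episodic": S})
        trips = cc.TripLog(
            trips=pd.DataFrame(
                {
                    "shopper_id": ["s"] * 3,
                    "timestep": [1, 2, 3],
                    "product_id": ["a", "b", "c"],
                    "iri_seconds": [np.nan, 1.0, 1.0],
                    "nav_method": ["search"] * 3,
                }
            )
        )
        res = analyses.permutation_similarity_test(trips, store, "episodic")
        assert res.cle == pytest.approx(0.5)
        assert res.p_value == 1.0


class TestLagProfile:
    def test_cued_trips_have_positive_mean_slope(self, small_sim):
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.0], n_shoppers=200, trip_length=15, seed=41
        )
        lp = analyses.lag_profile(trips, small_sim.store, "hierarchy")
        assert lp.mean_slope > 0
        assert lp.p_sign < 0.05

    def test_null_trips_ci_covers_zero(self, small_sim, null_trips):
        lp = analyses.lag_profile(null_trips, small_sim.store, "episodic")
        assert lp.ci_low <= 0 <= lp.ci_high

    def test_constant_similarity_gives_zero_slope(self):
        S = np.full((4, 4), 0.3)
        np.fill_diagonal(S, 1.0)
        store = cc.SimilarityStore(catalog=tuple("abcd"), matrices={"episodic": S})
        trips = cc.TripLog(
            trips=pd.DataFrame(
                {
                    "shopper_id": ["s"] * 4,
                    "timestep": range(1, 5),
                    "product_id": list("abcd"),
                    "iri_seconds": [np.nan, 1, 1, 1],
                    "nav_method": ["search"] * 4,
                }
            )
        )
        lp = analyses.lag_profile(trips, store, "episodic")
        assert lp.slopes[0] == 0.0

    def test_short_shoppers_excluded(self, toy_store):
        trips = cc.TripLog(
            trips=pd.DataFrame(
                {
                    "shopper_id": ["a", "a", "b", "b", "b"],
                    "timestep": [1, 2, 1, 2, 3],
                    "product_id": ["A", "B", "A", "C", "D"],
                    "iri_seconds": [np.nan, 1, np.nan, 1, 1],
                    "nav_method": ["search"] * 5,
                }
            )
        )
        lp = analyses.lag_profile(trips, toy_store, "episodic")
        assert lp.n_shoppers == 1 and lp.n_excluded == 1


class TestTimestepRegression:
    def test_model_trips_show_depletion(self, small_sim):
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.5], n_shoppers=150, trip_length=20, seed=51
        )
        reg = analyses.timestep_regression(trips, small_sim.store, "hierarchy")
        assert reg.coef("decile") < 0
        assert reg.ci("decile")[1] < 0

    def test_random_trips_ci_covers_zero(self, small_sim, null_trips):
        reg = analyses.timestep_regression(null_trips, small_sim.store, "hierarchy")
        lo, hi = reg.ci("decile")
        assert lo <= 0 <= hi

    def test_single_bin_rejected(self, toy_store):
        trips = cc.TripLog(
            trips=pd.DataFrame(
                {
                    "shopper_id": ["s", "s"],
                    "timestep": [1, 2],
                    "product_id": ["A", "B"],
                    "iri_seconds": [np.nan, 1.0],
                    "nav_method": ["search"] * 2,
                }
            )
        )
        with pytest.raises(ValueError, match="one decile"):
            analyses.timestep_regression(trips, toy_store, "episodic")


class TestIriRegression:
    def test_planted_signs_recovered(self, small_sim):
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.0], n_shoppers=150, trip_length=20, seed=61
        )
        reg = analyses.iri_regression(trips, small_sim.store)
        for rep in cc.REPRESENTATIONS:
            assert reg.coef(f"sim_{rep}") < 0, rep
        assert reg.coef("timestep") > 0

    def test_noise_free_limit_recovers_planted_values(self, small_sim):
        # sigma = 0: standardised coefficients equal the planted slopes
        # mapped through sd(S_k)/sd(IRI), to 3 decimals
        iri = cc.IriParams(intercept=40.0, slopes=(6.0, 3.0, 9.0),
                           timestep_slope=0.2, sigma=1e-9)
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.0], n_shoppers=80,
            trip_length=(10, 25), seed=62, iri=iri,
        )
        # exclude products_remaining: with the generative model linear in
        # timestep alone, it is redundant with timestep
        reg = analyses.iri_regression(
            trips, small_sim.store, covariates=("timestep",)
        )
        tab = analyses.transition_table(trips, small_sim.store)
        tab = tab[tab["iri_seconds"] > 0]
        sd_y = tab["iri_seconds"].std(ddof=0)
        for slope, rep in zip(iri.slopes, cc.REPRESENTATIONS):
            expected = -slope * tab[f"sim_{rep}"].std(ddof=0) / sd_y
            assert reg.coef(f"sim_{rep}") == pytest.approx(expected, abs=1e-3)
        expected_t = iri.timestep_slope * tab["timestep"].std(ddof=0) / sd_y
        assert reg.coef("timestep") == pytest.approx(expected_t, abs=1e-3)

    def test_shuffled_iris_show_nothing(self, small_sim):
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.0], n_shoppers=100, trip_length=15, seed=63
        )
        rng = np.random.default_rng(0)
        shuffled = trips.trips.copy()
        vals = shuffled["iri_seconds"].to_numpy().copy()
        rng.shuffle(vals)
        shuffled["iri_seconds"] = vals
        reg = analyses.iri_regression(
            cc.TripLog(trips=shuffled, shopper_errors=trips.shopper_errors),
            small_sim.store,
        )
        for rep in cc.REPRESENTATIONS:
            lo, hi = reg.ci(f"sim_{rep}")
            assert lo <= 0 <= hi, rep


class TestRegressionOracle:
    def test_ols_matches_normal_equations(self, small_sim):
        # variable trip lengths keep products_remaining and timestep
        # linearly independent
        trips, _ = make_trips(
            small_sim.store, [0.3, 0.1, 2.0], n_shoppers=40, trip_length=(10, 20), seed=71
        )
        reg = analyses.iri_regression(trips, small_sim.store)
        tab = analyses.transition_table(trips, small_sim.store)
        tab = tab[tab["iri_seconds"] > 0].reset_index(drop=True)

        def z(v):
            return (v - v.mean()) / v.std(ddof=0)

        cols = {f"sim_{r}": z(tab[f"sim_{r}"]) for r in cc.REPRESENTATIONS}
        cols["timestep"] = z(tab["timestep"].astype(float))
        cols["products_remaining"] = z(tab["products_remaining"].astype(float))
        nav = pd.get_dummies(tab["nav_method"].astype(str), prefix="nav", dtype=float)
        X = pd.concat([pd.DataFrame(cols), nav.iloc[:, 1:]], axis=1)
        Xd = np.column_stack([np.ones(len(X)), X.to_numpy()])
        y = z(tab["iri_seconds"]).to_numpy()
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        fitted = reg.params[["const", *X.columns]].to_numpy()
        assert np.abs(fitted - beta).max() < 1e-8


class TestErrorAnalysis:
    def _fits_frame(self, betas):
        df = pd.DataFrame(betas, columns=[f"beta_{r}" for r in cc.REPRESENTATIONS])
        df.insert(0, "shopper_id", [f"S{i:05d}" for i in range(len(df))])
        return df

    def test_planted_links_recovered_from_true_weights(self, small_sim):
        rng = np.random.default_rng(5)
        n = 500
        betas = rng.uniform([0, 0, 0], [0.5, 0.2, 4.0], size=(n, 3))
        cfg = cc.SimulationConfig(
            catalog_size=100, n_shoppers=n, trip_length=8,
            true_betas=betas, seed=81,
        )
        trips, true = cc.generate_trips(small_sim.store, cfg)
        res = analyses.error_analysis(
            self._fits_frame(betas), trips
        )
        sp = res["spearman"].set_index(["outcome", "predictor"])
        link = cfg.error_link
        for outcome, coefs in [("forgotten_count", link.forgotten),
                               ("removed_count", link.removed)]:
            for rep in cc.REPRESENTATIONS:
                rho = sp.loc[(outcome, f"beta_{rep}"), "rho"]
                assert np.sign(rho) == np.sign(coefs[rep]), (outcome, rep)

    def test_independent_counts_show_nothing(self, small_sim):
        rng = np.random.default_rng(6)
        n = 300
        betas = rng.uniform([0, 0, 0], [0.5, 0.2, 4.0], size=(n, 3))
        cfg = cc.SimulationConfig(
            catalog_size=100, n_shoppers=n, trip_length=6,
            true_betas=betas, seed=82,
            error_link=cc.ErrorLink(
                forgotten={"intercept": 0.5, "episodic": 0, "semantic": 0, "hierarchy": 0},
                removed={"intercept": 1.0, "episodic": 0, "semantic": 0, "hierarchy": 0},
            ),
        )
        trips, _ = cc.generate_trips(small_sim.store, cfg)
        res = analyses.error_analysis(self._fits_frame(betas), trips)
        for row in res["spearman"].itertuples():
            assert row.ci_low <= 0 <= row.ci_high

    def test_constant_weights_reported_not_applicable(self, small_sim):
        n = 20
        betas = np.tile([0.2, 0.1, 1.0], (n, 1))
        cfg = cc.SimulationConfig(
            catalog_size=100, n_shoppers=n, trip_length=5,
            true_betas=betas, seed=83,
        )
        trips, _ = cc.generate_trips(small_sim.store, cfg)
        res = analyses.error_analysis(self._fits_frame(betas), trips)
        assert res["spearman"]["rho"].isna().all()

    def test_spearman_self_correlation(self):
        x = np.arange(50, dtype=float)
        res = analyses._spearman_ci(x, x, "x", "x")
        assert res.rho == pytest.approx(1.0)


class TestNavFilter:
    def test_filter_changes_n_not_code_path(self, small_sim):
        full = analyses.lag_profile(small_sim.trips, small_sim.store, "episodic")
        search = analyses.lag_profile(
            small_sim.trips, small_sim.store, "episodic", nav_filter="search"
        )
        assert search.n_shoppers <= full.n_shoppers
        assert np.isfinite(search.mean_slope)

    def test_permutation_filter_runs(self, small_sim):
        res = analyses.permutation_similarity_test(
            small_sim.trips, small_sim.store, "episodic", seed=1, nav_filter=["search"]
        )
        assert res.n_true <= len(small_sim.trips.sequences())
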