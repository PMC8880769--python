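"""Descriptive and inferential analyses of ordered choice sequences.

Five questions, each answered by one public function:

* Are consecutive choices more similar than chance?
  (:func:`permutation_similarity_test` — trip-wise mean consecutive
  similarity versus randomly permuted orders, Mann-Whitney U with a
  common-language effect size.)
* Does similarity to the current choice decay with lag — the "ripple"
  of cued retrieval? (:func:`lag_profile` — per-shopper regressions of
  standardised mean similarity on lag, with a population sign test.)
* Do choices grow more dissimilar over the trip as high-similarity
  partners are used up? (:func:`timestep_regression`.)
* Are dissimilar successors slower to retrieve, and do responses slow
  over the trip? (:func:`iri_regression`.)
* Do the fitted attention weights predict retrieval errors — forgotten
  items (misses) and removed items (false alarms)?
  (:func:`error_analysis`.)

Every function accepts ``nav_filter`` to restrict trips to choices made
through particular navigation methods (e.g. search-bar only), running
the identical code path on the filtered subsequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import REPRESENTATIONS, SimilarityStore, TripLog

__all__ = [
    "PermutationResult",
    "LagProfile",
    "RegressionResult",
    "permutation_similarity_test",
    "lag_profile",
    "timestep_regression",
    "iri_regression",
    "error_analysis",
    "transition_table",
]

logger = logging.getLogger(__name__)


def _maybe_filter(trips: TripLog, nav_filter) -> TripLog:
    if nav_filter is None:
        return trips
    if isinstance(nav_filter, str):
        nav_filter = [nav_filter]
    return trips.filter_nav(nav_filter)


def _consecutive_mean(sim: np.ndarray, idx: np.ndarray) -> float:
    return float(sim[idx[:-1], idx[1:]].mean())


@dataclass
class PermutationResult:
    """True-order versus permuted-order consecutive-similarity comparison."""

    representation: str
    median_true: float
    iqr_true: float
    median_permuted: float
    iqr_permuted: float
    U: float
    p_value: float
    cle: float
    n_true: int
    n_permuted: int


def permutation_similarity_test(
    trips: TripLog,
    store: SimilarityStore,
    representation: str,
    n_shuffles: int = 1,
    seed: int = 0,
    nav_filter=None,
) -> PermutationResult:
    """Is within-trip consecutive similarity higher than under random order?

    For every trip the mean similarity between consecutive purchases is
    computed for the true order and for ``n_shuffles`` random
    permutations of the same products. The two samples of trip means are
    compared with a two-sided Mann-Whitney U; the common-language effect
    size ``CLE = U / (n1 * n2)`` is the probability a random true-order
    trip beats a random permuted one (ties counted half).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    trips = _maybe_filter(trips, nav_filter)
    sim = store.matrices[representation]
    rng = np.random.default_rng(seed)
    true_means, perm_means = [], []
    for seq in trips.sequences().values():
        if len(seq) < 2:
            continue
        idx = store.indices(seq)
        true_means.append(_consecutive_mean(sim, idx))
        for _ in range(n_shuffles):
            perm_means.append(_consecutive_mean(sim, rng.permutation(idx)))
    true_arr, perm_arr = np.asarray(true_means), np.asarray(perm_means)
    if len(true_arr) == 0:
        raise ValueError("no trips of length >= 2 after filtering")
    if np.ptp(np.concatenate([true_arr, perm_arr])) == 0:
        # degenerate: all similarities identical -> no effect by construction
        U = len(true_arr) * len(perm_arr) / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(true_arr, perm_arr, alternative="two-sided")
        U, p = float(res.statistic), float(res.pvalue)
    return PermutationResult(
        representation=representation,
        median_true=float(np.median(true_arr)),
        iqr_true=float(stats.iqr(true_arr)),
        median_permuted=float(np.median(perm_arr)),
        iqr_permuted=float(stats.iqr(perm_arr)),
        U=U,
        p_value=p,
        cle=U / (len(true_arr) * len(perm_arr)),
        n_true=len(true_arr),
        n_permuted=len(perm_arr),
    )


@dataclass
class LagProfile:
    """Per-shopper similarity-by-lag slopes and their population summary."""

    representation: str
    lags: np.ndarray  # e.g. -10..-1
    mean_by_lag: np.ndarray  # population mean of per-shopper standardised means
    slopes: np.ndarray  # one OLS slope per shopper
    mean_slope: float
    ci_low: float
    ci_high: float
    z_sign: float
    p_sign: float
    n_shoppers: int
    n_excluded: int


def lag_profile(
    trips: TripLog,
    store: SimilarityStore,
    representation: str,
    max_lag: int = 10,
    nav_filter=None,
) -> LagProfile:
    """The memory "ripple": similarity between a choice and earlier choices.

    For each shopper and lag ``-l`` the mean similarity of pairs
    ``(x_{t-l}, x_t)`` is computed over all valid ``t``, standardised
    within shopper across the available lags, and regressed on the lag
    value. A positive slope means more recent choices are more similar.
    The population report is the mean slope with a 95% CI and a
    two-sided exact sign test on slope signs (its normal-approximation
    Z is reported alongside).
    """
    trips = _maybe_filter(trips, nav_filter)
    sim = store.matrices[representation]
    lags = np.arange(-max_lag, 0)
    slopes = []
    z_means = []
    n_excluded = 0
    for seq in trips.sequences().values():
        if len(seq) < 3:
            n_excluded += 1
            logger.info("lag_profile: shopper excluded with %d choices", len(seq))
            continue
        idx = store.indices(seq)
        means, used = [], []
        for l in range(1, max_lag + 1):
            if l >= len(idx):
                break
            means.append(float(sim[idx[:-l], idx[l:]].mean()))
            used.append(-l)
        means_arr = np.array(means)[::-1]  # order lags -max..-1
        used_arr = np.array(used)[::-1]
        sd = means_arr.std()
        z = (means_arr - means_arr.mean()) / sd if sd > 0 else np.zeros_like(means_arr)
        slope = (
            0.0
            if sd == 0
            else float(np.polyfit(used_arr, z, 1)[0])
        )
        slopes.append(slope)
        if len(z) == max_lag:
            z_means.append(z)
    slopes_arr = np.asarray(slopes)
    m = float(slopes_arr.mean())
    half = (
        1.96 * slopes_arr.std(ddof=1) / math.sqrt(len(slopes_arr))
        if len(slopes_arr) > 1
        else math.nan
    )
    n_pos = int((slopes_arr > 0).sum())
    n_neg = int((slopes_arr < 0).sum())
    n_eff = n_pos + n_neg
    if n_eff > 0:
        p_sign = float(stats.binomtest(n_pos, n_eff, 0.5).pvalue)
        z_sign = (n_pos - n_eff / 2.0) / math.sqrt(n_eff / 4.0)
    else:
        p_sign, z_sign = 1.0, 0.0
    return LagProfile(
        representation=representation,
        lags=lags,
        mean_by_lag=np.mean(z_means, axis=0) if z_means else np.full(max_lag, np.nan),
        slopes=slopes_arr,
        mean_slope=m,
        ci_low=m - half,
        ci_high=m + half,
        z_sign=z_sign,
        p_sign=p_sign,
        n_shoppers=len(slopes_arr),
        n_excluded=n_excluded,
    )


@dataclass
class RegressionResult:
    """Standardised OLS summary: coefficients, CIs, p-values, fit stats."""

    outcome: str
    params: pd.Series
    conf_int: pd.DataFrame  # columns ["low", "high"]
    p_values: pd.Series
    r_squared: float
    f_statistic: float
    n: int

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def ci(self, name: str) -> tuple[float, float]:
        return float(self.conf_int.loc[name, "low"]), float(self.conf_int.loc[name, "high"])


def _standardize(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x * 0.0


def _run_ols(y: pd.Series, X: pd.DataFrame, outcome: str) -> RegressionResult:
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.OLS(y.to_numpy(dtype=float), Xc.to_numpy(dtype=float))
    res = model.fit()
    names = list(Xc.columns)
    ci = pd.DataFrame(res.conf_int(), index=names, columns=["low", "high"])
    return RegressionResult(
        outcome=outcome,
        params=pd.Series(res.params, index=names),
        conf_int=ci,
        p_values=pd.Series(res.pvalues, index=names),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue) if res.df_model > 0 else math.nan,
        n=int(res.nobs),
    )


def transition_table(
    trips: TripLog, store: SimilarityStore, nav_filter=None
) -> pd.DataFrame:
    """One row per cued transition with similarities, IRI, and covariates.

    ``products_remaining`` counts the items still to be purchased in the
    trip after the current choice. The navigation label is the method of
    the *destination* choice (how the shopper reached the item they
    added).
    """
    trips = _maybe_filter(trips, nav_filter)
    frames = []
    for sid, grp in trips.trips.groupby("shopper_id", sort=False):
        idx = store.indices(grp["product_id"])
        if len(idx) < 2:
            continue
        T = len(idx)
        row = {
            "shopper_id": sid,
            "timestep": grp["timestep"].to_numpy()[1:],
            "trip_length": T,
            "products_remaining": T - grp["timestep"].to_numpy()[1:],
            "iri_seconds": grp["iri_seconds"].to_numpy()[1:],
            "nav_method": grp["nav_method"].to_numpy()[1:],
        }
        for rep in store.names:
            row[f"sim_{rep}"] = store.matrices[rep][idx[:-1], idx[1:]]
        frames.append(pd.DataFrame(row))
    if not frames:
        raise ValueError("no transitions available")
    return pd.concat(frames, ignore_index=True)


def _nav_dummies(tab: pd.DataFrame) -> pd.DataFrame:
    nav = tab["nav_method"].fillna("unknown").astype(str)
    dummies = pd.get_dummies(nav, prefix="nav", dtype=float)
    # drop one level as the reference category
    return dummies.iloc[:, 1:] if dummies.shape[1] > 1 else dummies * 0.0


def timestep_regression(
    trips: TripLog,
    store: SimilarityStore,
    representation: str,
    n_bins: int = 10,
    nav_filter=None,
) -> RegressionResult:
    """Does consecutive similarity decline over the course of a trip?

    Transitions are binned into within-trip deciles of relative timestep
    (adjusting for different trip sizes); standardised similarity is
    regressed on the decile index with navigation-method indicators as
    confounds. A negative ``decile`` coefficient is the depletion
    signature of sampling without replacement.
    """
    tab = transition_table(trips, store, nav_filter=nav_filter)
    rel = (tab["timestep"] - 2) / np.maximum(tab["trip_length"] - 2, 1)
    tab["decile"] = np.minimum((rel * n_bins).astype(int), n_bins - 1) + 1
    if tab["decile"].nunique() < 2:
        raise ValueError("insufficient spread: all transitions fall in one decile bin")
    y = _standardize(tab[f"sim_{representation}"])
    X = pd.concat([tab[["decile"]].astype(float), _nav_dummies(tab)], axis=1)
    return _run_ols(y, X, outcome=f"sim_{representation}")


DEFAULT_IRI_COVARIATES = ("timestep", "products_remaining")


def iri_regression(
    trips: TripLog,
    store: SimilarityStore,
    covariates=DEFAULT_IRI_COVARIATES,
    nav_filter=None,
) -> RegressionResult:
    """Standardised OLS of inter-response intervals on the similarities.

    Predictors are the three consecutive-choice similarities plus the
    configured covariates (timestep and products-remaining by default)
    and navigation indicators. All continuous variables are z-scored, so
    coefficients are standardised. Non-positive or missing IRIs are
    dropped (count logged): the first choice of a trip has no IRI.
    """
    tab = transition_table(trips, store, nav_filter=nav_filter)
    bad = ~(tab["iri_seconds"] > 0)
    if bad.any():
        logger.info("iri_regression: dropping %d non-positive/missing IRIs", int(bad.sum()))
    tab = tab[~bad].reset_index(drop=True)
    y = _standardize(tab["iri_seconds"])
    cols = {}
    for rep in store.names:
        cols[f"sim_{rep}"] = _standardize(tab[f"sim_{rep}"])
    for cov in covariates:
        cols[cov] = _standardize(tab[cov].astype(float))
    X = pd.concat([pd.DataFrame(cols), _nav_dummies(tab)], axis=1)
    return _run_ols(y, X, outcome="iri_seconds")


@dataclass
class SpearmanResult:
    """Rank correlation with a Fisher-z 95% confidence interval."""

    predictor: str
    outcome: str
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def _spearman_ci(x: np.ndarray, y: np.ndarray, predictor: str, outcome: str) -> SpearmanResult:
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return SpearmanResult(predictor, outcome, math.nan, math.nan, math.nan, math.nan, n)
    rho, p = stats.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.06 / math.sqrt(n - 3) if n > 3 else math.nan
    return SpearmanResult(
        predictor,
        outcome,
        float(rho),
        float(np.tanh(z - 1.96 * se)),
        float(np.tanh(z + 1.96 * se)),
        float(p),
        n,
    )


def error_analysis(
    fits: pd.DataFrame,
    trips: TripLog,
) -> dict:
    """Do fitted attention weights predict forgetting and removal errors?

    ``fits`` is the per-shopper full-model fit table (one row per
    shopper, ``beta_*`` columns). For each error count the function
    reports (a) the Spearman correlation of every attention weight with
    the count, with Fisher-z CIs, and (b) a multiple regression of the
    count on the scaled weights with the number of choices and the
    per-shopper navigation-method shares as confounds.
    """
    if trips.shopper_errors is None:
        raise ValueError("trip log carries no per-shopper error counts")
    per = fits.drop_duplicates("shopper_id").set_index("shopper_id")
    counts = trips.shopper_errors.set_index("shopper_id")
    n_choices = trips.trips.groupby("shopper_id").size().rename("n_choices")
    shares = (
        trips.trips.groupby("shopper_id")["nav_method"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .add_prefix("share_")
    )
    df = per.join([counts, n_choices, shares], how="inner").reset_index()

    out: dict = {"spearman": [], "regressions": {}}
    beta_cols = [f"beta_{r}" for r in REPRESENTATIONS]
    for outcome in ("forgotten_count", "removed_count"):
        for col in beta_cols:
            out["spearman"].append(
                _spearman_ci(
                    df[col].to_numpy(), df[outcome].to_numpy(), col, outcome
                )
            )
        cols = {c: _standardize(df[c]) for c in beta_cols}
        cols["n_choices"] = _standardize(df["n_choices"].astype(float))
        for c in df.columns:
            if c.startswith("share_"):
                cols[c] = _standardize(df[c])
        # drop any zero-variance confounds (e.g. a nav share that is constant)
        X = pd.DataFrame({k: v for k, v in cols.items() if v.std(ddof=0) > 0 or k in beta_cols})
        out["regressions"][outcome] = _run_ols(
            df[outcome].astype(float), X, outcome=outcome
        )
    out["spearman"] = pd.DataFrame([vars(s) for s in out["spearman"]])
    return out
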