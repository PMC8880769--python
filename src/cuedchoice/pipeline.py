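"""End-to-end pipeline driver: simulate/load -> store -> fits -> analyses.

A :class:`PipelineConfig` either points at real data files (trips,
taxonomy, basket corpus) or embeds a :class:`SimulationConfig`; exactly
one of the two must be active. Each stage writes its outputs under the
configured directory and the run finishes with a provenance manifest.
A stage failure is recorded in the manifest and later stages that
depend on it are skipped; earlier outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import analyses, clustering, io, representations, retrieval, synthetic
from .containers import REPRESENTATIONS, InvalidConfigError

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "results"
    seed: int = 0
    # exactly one input mode
    simulation: synthetic.SimulationConfig | None = None
    trips_path: str | None = None
    taxonomy_path: str | None = None
    corpus_path: str | None = None
    errors_path: str | None = None
    # stage options
    embedding_method: str = "ppmi_svd"
    embedding_dimension: int = 50
    epsilon: float = 1e-6
    n_restarts: int = 5
    run_comparison: bool = True
    run_analyses: bool = True
    run_clustering: bool = True
    clustering_level: int = 4
    nav_filter: list[str] | None = None

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.trips_path, self.taxonomy_path, self.corpus_path))
        if (self.simulation is None) == (not real):
            raise InvalidConfigError(
                "exactly one of {simulation config, real-data paths} must be set"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages, returning a bundle of in-memory results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    bundle: dict = {}

    def _stage(name: str, fn):
        try:
            result = fn()
            stages[name] = "ok"
            return result
        except Exception as exc:  # preserve partial results, mark the stage
            logger.exception("stage %s failed", name)
            stages[name] = f"failed: {exc}"
            return None

    def _inputs():
        if config.simulation is not None:
            sim = synthetic.simulate(config.simulation.with_seed(config.seed))
            io.write_taxonomy(sim.taxonomy, out / "taxonomy.csv")
            io.write_corpus(sim.corpus, out / "baskets.csv")
            io.write_trips(sim.trips, out / "trips.csv", out / "shopper_errors.csv")
            sim.true_betas.to_csv(out / "true_betas.csv", index=False)
            return sim.taxonomy, sim.corpus, sim.trips, sim.store
        taxonomy = io.read_taxonomy(config.taxonomy_path)
        corpus = io.read_corpus(config.corpus_path)
        trips = io.read_trips(config.trips_path, errors_path=config.errors_path)
        return taxonomy, corpus, trips, None

    loaded = _stage("inputs", _inputs)
    if loaded is None:
        io.write_manifest(out, config, config.seed, stages)
        return {"stages": stages}
    taxonomy, corpus, trip_log, store = loaded

    if store is None:
        store = _stage(
            "store",
            lambda: representations.build_store(
                corpus,
                taxonomy,
                embedding_method=config.embedding_method,
                embedding_dimension=config.embedding_dimension,
                seed=config.seed,
            ),
        )
    else:
        stages["store"] = "ok"
    if store is not None:
        io.write_store(store, out / "store")
        bundle["store"] = store

        fits = _stage(
            "fits",
            lambda: retrieval.fit_population(
                trip_log,
                store,
                REPRESENTATIONS,
                epsilon=config.epsilon,
                n_restarts=config.n_restarts,
                seed=config.seed,
            ),
        )
        if fits is not None:
            fits.to_csv(out / "fits_full_model.csv", index=False)
            bundle["fits"] = fits

        if config.run_comparison:
            cmp = _stage(
                "comparison",
                lambda: retrieval.compare_models(
                    trip_log,
                    store,
                    epsilon=config.epsilon,
                    n_restarts=config.n_restarts,
                    seed=config.seed,
                ),
            )
            if cmp is not None:
                per_fit, summary = cmp
                per_fit.to_csv(out / "model_fits.csv", index=False)
                summary.to_csv(out / "model_comparison.csv", index=False)
                bundle["comparison"] = summary

        if config.run_analyses:
            def _run_analyses():
                res: dict = {}
                perm_rows = []
                for rep in REPRESENTATIONS:
                    perm_rows.append(
                        dataclasses.asdict(
                            analyses.permutation_similarity_test(
                                trip_log, store, rep, seed=config.seed,
                                nav_filter=config.nav_filter,
                            )
                        )
                    )
                res["permutation"] = pd.DataFrame(perm_rows)
                res["permutation"].to_csv(out / "permutation_tests.csv", index=False)
                lag_rows = []
                for rep in REPRESENTATIONS:
                    lp = analyses.lag_profile(
                        trip_log, store, rep, nav_filter=config.nav_filter
                    )
                    lag_rows.append(
                        {
                            "representation": rep,
                            "mean_slope": lp.mean_slope,
                            "ci_low": lp.ci_low,
                            "ci_high": lp.ci_high,
                            "z_sign": lp.z_sign,
                            "p_sign": lp.p_sign,
                            "n_shoppers": lp.n_shoppers,
                        }
                    )
                res["lag"] = pd.DataFrame(lag_rows)
                res["lag"].to_csv(out / "lag_profiles.csv", index=False)
                iri = analyses.iri_regression(trip_log, store, nav_filter=config.nav_filter)
                iri.params.rename("coef").to_csv(out / "iri_regression.csv")
                res["iri"] = iri
                if bundle.get("fits") is not None and trip_log.shopper_errors is not None:
                    err = analyses.error_analysis(bundle["fits"], trip_log)
                    err["spearman"].to_csv(out / "error_spearman.csv", index=False)
                    res["errors"] = err
                return res

            res = _stage("analyses", _run_analyses)
            if res is not None:
                bundle["analyses"] = res

        if config.run_clustering:
            def _run_clustering():
                level = min(config.clustering_level, taxonomy.depth)
                tm = clustering.transition_lift(
                    trip_log, taxonomy, level, nav_filter=config.nav_filter
                )
                sol = clustering.spectral_cluster(tm, seed=config.seed)
                pd.DataFrame(
                    {"group": list(sol.assignment), "cluster": list(sol.assignment.values())}
                ).to_csv(out / "transition_clusters.csv", index=False)
                # heatmap ordering: groups sorted by cluster then name
                order = sorted(sol.assignment, key=lambda g: (sol.assignment[g], g))
                (out / "heatmap_order.txt").write_text("\n".join(order) + "\n")
                return tm, sol

            clus = _stage("clustering", _run_clustering)
            if clus is not None:
                bundle["clustering"] = clus

    io.write_manifest(out, config, config.seed, stages)
    bundle["stages"] = stages
    return bundle
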