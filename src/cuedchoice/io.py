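"""Readers, writers, configuration, and provenance manifests.

All interchange is plain CSV/JSON/YAML:

* trips — ``shopper_id, timestep, product_id, iri_seconds, nav_method``
  (1-based consecutive timesteps per shopper), plus an optional
  per-shopper errors CSV ``shopper_id, removed_count, forgotten_count``;
* taxonomy — ``product_id, level1..levelD``;
* basket corpus — long format ``basket_id, product_id``;
* similarity store — one CSV per matrix with the catalog as header
  row/column, and a JSON sidecar with catalog order and build
  parameters.

Writers stamp a ``manifest.json`` next to their outputs recording the
seed, a hash of the configuration, and a content hash per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BasketCorpus, SimilarityStore, Taxonomy, TripLog
from .synthetic import ErrorLink, IriParams, SimulationConfig

__all__ = [
    "read_trips",
    "write_trips",
    "read_taxonomy",
    "write_taxonomy",
    "read_corpus",
    "write_corpus",
    "read_store",
    "write_store",
    "load_simulation_config",
    "config_hash",
    "write_manifest",
]

TRIP_COLUMNS = list(TripLog.REQUIRED)


class SchemaError(ValueError):
    """An input file is missing required structure."""


def _require_columns(frame: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_trips(path, errors_path=None) -> TripLog:
    """Load a trip log CSV, validating schema and trip structure."""
    frame = pd.read_csv(path)
    _require_columns(frame, TRIP_COLUMNS, "trip table")
    frame["shopper_id"] = frame["shopper_id"].astype(str)
    frame["product_id"] = frame["product_id"].astype(str)
    errors = None
    if errors_path is not None:
        errors = pd.read_csv(errors_path)
        _require_columns(
            errors, ["shopper_id", "removed_count", "forgotten_count"], "errors table"
        )
        errors["shopper_id"] = errors["shopper_id"].astype(str)
    return TripLog(trips=frame, shopper_errors=errors)


def write_trips(trip_log: TripLog, path, errors_path=None) -> None:
    trip_log.trips.to_csv(path, index=False)
    if errors_path is not None and trip_log.shopper_errors is not None:
        trip_log.shopper_errors.to_csv(errors_path, index=False)


def read_taxonomy(path) -> Taxonomy:
    return Taxonomy.from_frame(pd.read_csv(path, dtype=str))


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    taxonomy.to_frame().to_csv(path, index=False)


def read_corpus(path, catalog=None) -> BasketCorpus:
    frame = pd.read_csv(path)
    _require_columns(frame, ["basket_id", "product_id"], "basket corpus")
    return BasketCorpus.from_frame(frame, catalog=catalog)


def write_corpus(corpus: BasketCorpus, path) -> None:
    corpus.to_frame().to_csv(path, index=False)


def write_store(store: SimilarityStore, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, m in store.matrices.items():
        pd.DataFrame(m, index=store.catalog, columns=store.catalog).to_csv(
            directory / f"{name}.csv"
        )
    sidecar = {
        "catalog": list(store.catalog),
        "matrices": sorted(store.matrices),
        "provenance": store.provenance,
    }
    (directory / "store.json").write_text(json.dumps(sidecar, indent=2))


def read_store(directory) -> SimilarityStore:
    directory = Path(directory)
    sidecar = json.loads((directory / "store.json").read_text())
    catalog = tuple(sidecar["catalog"])
    matrices = {}
    for name in sidecar["matrices"]:
        frame = pd.read_csv(directory / f"{name}.csv", index_col=0)
        if tuple(frame.index) != catalog or tuple(frame.columns) != catalog:
            raise SchemaError(f"store matrix {name!r} does not match catalog order")
        matrices[name] = frame.to_numpy(dtype=float)
    return SimilarityStore(
        catalog=catalog, matrices=matrices, provenance=sidecar.get("provenance", {})
    )


def load_simulation_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML or JSON mapping."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError("simulation config must be a mapping")
    if "iri" in raw:
        raw["iri"] = IriParams(**{**raw["iri"], "slopes": tuple(raw["iri"].get("slopes", IriParams().slopes))})
    if "error_link" in raw:
        raw["error_link"] = ErrorLink(**raw["error_link"])
    for key in ("branching", "goals_per_basket", "trip_length"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration object.

    The output location is excluded so the hash identifies the scientific
    configuration, not where its results land.
    """
    payload = _jsonable(config)
    if isinstance(payload, dict):
        payload = {k: v for k, v in payload.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(directory, config, seed: int, stages: dict) -> Path:
    """Record seed, config hash, stage status, and per-file content hashes."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "stages": stages,
        "files": {str(p.relative_to(directory)): _file_hash(p) for p in files},
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
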