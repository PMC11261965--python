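"""Delimited-table, config and archive I/O.

All human-facing artifacts are header-bearing tab-separated tables:
parameters as long tables indexed by (i, j, k), contexts and observations
as wide per-experiment tables.  Trained states (variational posteriors,
surrogates) go to binary archives with a version header.  Run configuration
is YAML.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .onestep import CellContext, ModelParameters, ModelShape
from .posterior import VariationalPosterior
from .synthetic import Dataset

ARCHIVE_VERSION = 1
_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


# ---------------------------------------------------------------------------
# parameter / context / observation tables

def write_parameters(params: ModelParameters, path) -> None:
    nA, nL, nB = params.K.shape
    i, j, k = np.meshgrid(range(nA), range(nL), range(nB), indexing="ij")
    df = pd.DataFrame({
        "i": i.ravel(), "j": j.ravel(), "k": k.ravel(),
        "K": params.K.ravel(), "eps": params.eps.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_parameters(path) -> ModelParameters:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("i", "j", "k", "K", "eps"):
        if col not in df.columns:
            raise ValidationError(f"parameter table missing column {col!r}")
    shape = (df["i"].max() + 1, df["j"].max() + 1, df["k"].max() + 1)
    K = np.zeros(shape)
    eps = np.zeros(shape)
    K[df["i"], df["j"], df["k"]] = df["K"]
    eps[df["i"], df["j"], df["k"]] = df["eps"]
    return ModelParameters(K=K, eps=eps)


def _context_columns(shape: ModelShape) -> list[str]:
    return ([f"A{i}" for i in range(shape.nA)]
            + [f"B{k}" for k in range(shape.nB)]
            + [f"L{j}" for j in range(shape.nL)])


def write_contexts(contexts: list[CellContext], path) -> None:
    if not contexts:
        raise ValidationError("no contexts to write")
    shape = contexts[0].shape
    rows = [c.features() for c in contexts]
    df = pd.DataFrame(rows, columns=_context_columns(shape))
    df.insert(0, "experiment", range(len(contexts)))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_contexts(path) -> list[CellContext]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    a_cols = [c for c in df.columns if c.startswith("A")]
    b_cols = [c for c in df.columns if c.startswith("B")]
    l_cols = [c for c in df.columns if c.startswith("L")]
    if not (a_cols and b_cols and l_cols):
        raise ValidationError("context table must have A*, B* and L* columns")
    return [
        CellContext(A0=row[a_cols].to_numpy(float),
                    B0=row[b_cols].to_numpy(float),
                    L0=row[l_cols].to_numpy(float))
        for _, row in df.iterrows()
    ]


def write_observations(obs: np.ndarray, path) -> None:
    df = pd.DataFrame({"experiment": range(len(obs)), "x": np.asarray(obs, float)})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_observations(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "x" not in df.columns:
        raise ValidationError("observation table missing column 'x'")
    return df["x"].to_numpy(float)


def write_dataset(dataset: Dataset, directory) -> dict:
    """Write contexts, observations and meta under ``directory``; return paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "contexts": directory / "contexts.tsv",
        "observations": directory / "observations.tsv",
        "meta": directory / "dataset_meta.json",
    }
    write_contexts(dataset.contexts, paths["contexts"])
    write_observations(dataset.observations, paths["observations"])
    paths["meta"].write_text(json.dumps(_jsonable(dataset.meta), indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


def read_dataset(directory) -> Dataset:
    directory = Path(directory)
    contexts = read_contexts(directory / "contexts.tsv")
    obs = read_observations(directory / "observations.tsv")
    meta_path = directory / "dataset_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Dataset(contexts=contexts, observations=obs, meta=meta)


# ---------------------------------------------------------------------------
# trained-state archives

def save_posterior(posterior: VariationalPosterior, path) -> None:
    np.savez(
        path,
        version=ARCHIVE_VERSION,
        mu=posterior.mu,
        chol=posterior.chol,
        low_log10=posterior.low_log10,
        high_log10=posterior.high_log10,
        elbo_trace=np.asarray(posterior.elbo_trace, dtype=float),
    )


def load_posterior(path) -> VariationalPosterior:
    with np.load(path) as z:
        if int(z["version"]) != ARCHIVE_VERSION:
            raise ValidationError(f"unsupported posterior archive version {z['version']}")
        return VariationalPosterior(
            mu=z["mu"], chol=z["chol"],
            low_log10=float(z["low_log10"]), high_log10=float(z["high_log10"]),
            elbo_trace=list(z["elbo_trace"]),
        )


def save_surrogate(surrogate, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"version": ARCHIVE_VERSION, "surrogate": surrogate}, fh)


def load_surrogate(path):
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("version") != ARCHIVE_VERSION:
        raise ValidationError(f"unsupported surrogate archive version {blob.get('version')}")
    return blob["surrogate"]


# ---------------------------------------------------------------------------
# config

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(_jsonable(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
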