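"""Plain-text readers/writers for logs, worlds, and feature matrices."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .features import FeatureMatrices
from .lexicon import Lexicon
from .synthetic import World
from .config import WorldConfig

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def write_logs_tsv(records: pd.DataFrame, path) -> None:
    """Logs as TSV: user_id, iso-timestamp (UTC), lat, lon, joined tokens."""
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["ts"], unit="s").dt.strftime(_TS_FMT)
    df["text"] = [" ".join(t) for t in df["tokens"]]
    df[["user_id", "timestamp", "lat", "lon", "text"]].to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_logs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"user_id": str, "text": str})
    ts = pd.to_datetime(df["timestamp"], format=_TS_FMT, utc=True)
    out = pd.DataFrame({
        "user_id": df["user_id"],
        "ts": (ts.astype("int64") // 10**9).astype("int64"),
        "lat": df["lat"], "lon": df["lon"],
        "tokens": [tuple(str(t).split()) for t in df["text"]],
    })
    return out.sort_values(["user_id", "ts"], kind="mergesort").reset_index(drop=True)


def write_world_json(world: World, path) -> None:
    data = {
        "facilities": world.facilities.to_dict(orient="records"),
        "landmarks": world.landmarks.to_dict(orient="records"),
        "lexicon": world.lexicon.to_dict(),
        "term_truth": world.term_truth,
        "filler_tokens": world.filler_tokens,
        "filler_weights": list(map(float, world.filler_weights)),
        "config": {
            "n_facilities": world.config.n_facilities,
            "n_landmarks": world.config.n_landmarks,
            "n_landmark_categories": world.config.n_landmark_categories,
            "map_extent": list(world.config.map_extent),
            "lexicon_size": world.config.lexicon_size,
            "n_filler_tokens": world.config.n_filler_tokens,
            "device_noise_rate": world.config.device_noise_rate,
            "seed": world.config.seed,
        },
    }
    Path(path).write_text(json.dumps(data))


def read_world_json(path) -> World:
    import numpy as np
    data = json.loads(Path(path).read_text())
    cfg = data["config"]
    cfg["map_extent"] = tuple(cfg["map_extent"])
    return World(
        facilities=pd.DataFrame(data["facilities"]),
        landmarks=pd.DataFrame(data["landmarks"]),
        lexicon=Lexicon.from_dict(data["lexicon"]),
        term_truth={k: bool(v) for k, v in data["term_truth"].items()},
        filler_tokens=list(data["filler_tokens"]),
        filler_weights=np.asarray(data["filler_weights"]),
        config=WorldConfig(**cfg),
    )


def write_matrices(matrices: FeatureMatrices, outdir) -> None:
    """Matrices as CSV plus a JSON sidecar with the column->category map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices.daywise.to_csv(outdir / "daywise.csv")
    matrices.aggregate.to_csv(outdir / "aggregate.csv")
    sidecar = {
        "daywise_categories": matrices.daywise_categories,
        "aggregate_categories": matrices.aggregate_categories,
    }
    (outdir / "columns.json").write_text(json.dumps(sidecar))


def read_matrices(outdir) -> FeatureMatrices:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "columns.json").read_text())
    return FeatureMatrices(
        daywise=pd.read_csv(outdir / "daywise.csv", index_col="user_id"),
        aggregate=pd.read_csv(outdir / "aggregate.csv", index_col="user_id"),
        daywise_categories=sidecar["daywise_categories"],
        aggregate_categories=sidecar["aggregate_categories"],
    )
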