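"""Plain-text readers and writers.

Two dialects carry beat data:

* ``beat_text`` — one beat occurrence time (seconds) per line; blank lines
  and ``#`` comments allowed.
* ``rr_csv`` — two columns ``t_seconds,rr_seconds`` with header; ``t_seconds``
  is the time of the beat terminating each interval, so the beat sequence is
  reconstructed by anchoring the first beat at ``t[0] − rr[0]``.

Numbers are written at 12 significant digits, which round-trips every value
this pipeline produces bit-stably at that precision.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .features import FeatureMatrix, canonical_features
from .rr_timeseries import BeatSequence, RRSeries

__all__ = [
    "read_beats",
    "write_beats",
    "write_rr_csv",
    "read_rr_csv",
    "write_feature_table",
    "read_feature_table",
    "write_manifest",
]

_FMT = "%.12g"


def read_beats(path, dialect: str = "beat_text", label: str = "unlabeled") -> BeatSequence:
    """Load a validated beat sequence from either dialect."""
    path = Path(path)
    if dialect == "beat_text":
        times = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                times.append(float(line))
            except ValueError:
                raise ParseError(f"{path.name}:{lineno}: not a number: {raw!r}") from None
        return BeatSequence(times=np.asarray(times), label=label, record_id=path.stem)
    if dialect == "rr_csv":
        rr = read_rr_csv(path, label=label)
        times = np.concatenate(
            [[rr.timestamps[0] - rr.values[0]], rr.timestamps]
        )
        return BeatSequence(times=times, label=label, record_id=path.stem)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_beats(path, beats: BeatSequence) -> None:
    path = Path(path)
    lines = [_FMT % t for t in beats.times]
    path.write_text("\n".join(lines) + "\n")


def write_rr_csv(path, series: RRSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("t_seconds,rr_seconds\n")
        for t, v in zip(series.timestamps, series.values):
            fh.write(f"{_FMT % t},{_FMT % v}\n")


def read_rr_csv(path, label: str = "unlabeled") -> RRSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    for col in ("t_seconds", "rr_seconds"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing column {col!r}")
    rr = df["rr_seconds"].to_numpy(dtype=float)
    bad = np.flatnonzero(rr <= 0)
    if bad.size:
        raise ParseError(
            f"{path.name}: non-positive RR interval at data row {int(bad[0]) + 1}"
        )
    return RRSeries(
        values=rr,
        timestamps=df["t_seconds"].to_numpy(dtype=float),
        order=0,
        label=label,
        record_id=path.stem,
    )


def write_feature_table(path, features: FeatureMatrix) -> None:
    features.data.to_csv(path, index=False, float_format=_FMT)


def read_feature_table(path, max_order: int = 10) -> FeatureMatrix:
    df = pd.read_csv(path)
    expected = ["record_id", "label"] + [f.column for f in canonical_features(max_order)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing columns {missing}")
    return FeatureMatrix(data=df[expected], max_order=max_order)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, config: dict, inputs: list | None = None) -> None:
    """Run manifest: config, seeds, input digests, versions — exact replay."""
    manifest = {
        "schema_version": 1,
        "rrgamma_version": __version__,
        "python": platform.python_version(),
        "config": config,
        "inputs": [
            {"path": str(p), "sha256_16": file_digest(p)} for p in (inputs or [])
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
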