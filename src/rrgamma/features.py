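"""Scalar state variables of (derived) tachograms.

Each series — the tachogram and its first ``max_order`` derivatives — is
reduced by two operators, the arithmetic mean and the standard deviation
(square root of the unbiased, n−1 denominator, sample variance).  With
max_order = 10 this yields the 22-variable state space used throughout:
``mean_d0 .. mean_d10, sd_d0 .. sd_d10`` (canonical order).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientData
from .rr_timeseries import BeatSequence, DerivativeStack, RRSeries, beats_to_rr, derivative_stack

__all__ = [
    "FeatureName",
    "FeatureVector",
    "FeatureMatrix",
    "canonical_features",
    "series_mean",
    "series_std",
    "extract_features",
    "extract_feature_table",
    "correlation_matrix",
]

MAX_ORDER_DEFAULT = 10


class FeatureName(NamedTuple):
    """One state variable: an operator applied to one derivative order."""

    operator: str  # "mean" | "sd"
    order: int

    @property
    def column(self) -> str:
        return f"{self.operator}_d{self.order}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        op, _, tail = name.partition("_d")
        if op not in ("mean", "sd") or not tail.isdigit():
            raise ValueError(f"not a feature name: {name!r}")
        return cls(op, int(tail))


def canonical_features(max_order: int = MAX_ORDER_DEFAULT) -> list[FeatureName]:
    """MEAN 0..max_order then SD 0..max_order — the fixed column order."""
    return [FeatureName(op, k) for op in ("mean", "sd") for k in range(max_order + 1)]


@dataclass(frozen=True)
class FeatureVector:
    values: dict  # FeatureName -> float
    label: str = "unlabeled"
    record_id: str = ""

    def __getitem__(self, name: FeatureName) -> float:
        return self.values[name]


@dataclass
class FeatureMatrix:
    """Samples × state variables, with labels, backed by a DataFrame.

    Columns are ``record_id``, ``label``, then the canonical feature columns.
    """

    data: pd.DataFrame
    max_order: int = MAX_ORDER_DEFAULT

    @property
    def feature_names(self) -> list[FeatureName]:
        return canonical_features(self.max_order)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    def values(self, subset: Sequence[FeatureName] | None = None) -> np.ndarray:
        names = subset if subset is not None else self.feature_names
        return self.data[[f.column for f in names]].to_numpy(dtype=float)

    def group(self, label: str, subset: Sequence[FeatureName] | None = None) -> np.ndarray:
        names = subset if subset is not None else self.feature_names
        sub = self.data[self.data["label"] == label]
        return sub[[f.column for f in names]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def series_mean(s: RRSeries | np.ndarray) -> float:
    values = s.values if isinstance(s, RRSeries) else np.asarray(s, dtype=float)
    if len(values) < 1:
        raise InsufficientData("mean of an empty series")
    return float(np.mean(values))


def series_std(s: RRSeries | np.ndarray) -> float:
    """sqrt of the unbiased (n−1) sample variance."""
    values = s.values if isinstance(s, RRSeries) else np.asarray(s, dtype=float)
    if len(values) < 2:
        raise InsufficientData("sample SD needs >= 2 values")
    return float(np.std(values, ddof=1))


def extract_features(beats: BeatSequence, max_order: int = MAX_ORDER_DEFAULT) -> FeatureVector:
    """Mean and SD of every derivative order 0..max_order of the tachogram.

    Requires the tachogram to keep at least 2 samples at the top order, i.e.
    at least ``max_order + 3`` beats.
    """
    rr = beats_to_rr(beats)
    if len(rr) < max_order + 2:
        raise InsufficientData(
            f"{len(rr)} intervals cannot support SD at order {max_order} "
            f"(record {beats.record_id!r})"
        )
    stack = derivative_stack(rr, max_order)
    values = {}
    for k in range(max_order + 1):
        values[FeatureName("mean", k)] = series_mean(stack[k])
        values[FeatureName("sd", k)] = series_std(stack[k])
    return FeatureVector(values=values, label=beats.label, record_id=beats.record_id)


def extract_feature_table(
    sequences: Iterable[BeatSequence], max_order: int = MAX_ORDER_DEFAULT
) -> FeatureMatrix:
    """Feature matrix over a collection of labelled beat sequences."""
    rows = []
    for beats in sequences:
        fv = extract_features(beats, max_order)
        row = {"record_id": fv.record_id, "label": fv.label}
        row.update({name.column: v for name, v in fv.values.items()})
        rows.append(row)
    if not rows:
        raise InsufficientData("no sequences supplied")
    cols = ["record_id", "label"] + [f.column for f in canonical_features(max_order)]
    return FeatureMatrix(data=pd.DataFrame(rows, columns=cols), max_order=max_order)


def correlation_matrix(stack: DerivativeStack) -> np.ndarray:
    """|Pearson r| between every pair of derivative orders.

    Orders have different lengths; a pair is aligned on its shared leading
    timestamps (the longer series' tail is trimmed).  Zero-variance series
    give NaN entries — degeneracy is reported, not hidden as 0.
    """
    m = stack.max_order + 1
    out = np.full((m, m), np.nan)
    for i, j in itertools.combinations_with_replacement(range(m), 2):
        n = min(len(stack[i]), len(stack[j]))
        if n < 2:
            continue
        a = stack[i].values[:n]
        b = stack[j].values[:n]
        if np.all(a == a[0]) or np.all(b == b[0]):
            continue  # zero variance: leave NaN
        r = abs(float(np.corrcoef(a, b)[0, 1]))
        out[i, j] = out[j, i] = min(r, 1.0)
    for i in range(m):
        v = stack[i].values
        if len(v) >= 2 and not np.all(v == v[0]):
            out[i, i] = 1.0
    return out
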