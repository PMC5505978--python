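"""Perturbation models for beat sequences.

Four corruption mechanisms mimic what embedded R-peak detectors do to real
recordings:

* **TU** — timing uncertainty: each detected peak is shifted by an independent
  uniform draw on [−T, T] (T in milliseconds at the interface).
* **MB** — missing beats: a fraction u of beats, chosen uniformly without
  replacement, is discarded.
* **PAC** — premature atrial contraction: an extra beat b̃ is inserted in a
  gap (b_i, b_{i+1}), at least 200 ms from either side, and every later beat
  is shifted forward by (b̃ − b_i) — the rhythm resets.
* **PVC** — premature ventricular contraction: b̃ is inserted the same way
  but the next scheduled beat b_{i+1} is deleted (compensatory pause); the
  beat count is unchanged.

Event counts are round(u·L) with L the *original* beat count.  Insertions are
applied sequentially with gap eligibility recomputed after each event; a gap
is eligible when its interval exceeds 400 ms.  All randomness flows from one
seeded generator; a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EligibilityExhausted, InsufficientData, PerturbationCollision
from .rr_timeseries import BeatSequence

__all__ = [
    "PerturbationSpec",
    "PooledNoisySpec",
    "TU_POOL_MS",
    "MB_POOL",
    "ECTOPY_POOL",
    "jitter_beats",
    "drop_beats",
    "insert_pac",
    "insert_pvc",
    "apply_perturbation",
    "build_pooled_noisy",
]

# parameter pools used in the robustness sweeps
TU_POOL_MS = (1, 2, 3, 4, 5, 10, 15, 20, 30, 40, 50, 100)
MB_POOL = (0.01, 0.02, 0.03, 0.04, 0.05, 0.10, 0.15, 0.20, 0.30)
ECTOPY_POOL = (0.01, 0.02, 0.03, 0.04, 0.05, 0.10, 0.15, 0.20, 0.30)
# the pooled noisy database draws MB from its first 8 values (up to 20%)
POOLED_MB_POOL = MB_POOL[:8]

MIN_ECTOPIC_MARGIN = 0.2  # s; ectopic beat keeps 200 ms from both neighbours


@dataclass(frozen=True)
class PerturbationSpec:
    """One corruption: its kind and the single parameter that kind takes."""

    kind: str  # "TU" | "MB" | "PAC" | "PVC"
    T_ms: float | None = None  # TU only
    u: float | None = None  # MB / PAC / PVC only
    seed: int | None = None

    def __post_init__(self):
        if self.kind == "TU":
            if self.T_ms is None or self.T_ms <= 0 or self.u is not None:
                raise ValueError("TU takes exactly T_ms > 0")
        elif self.kind in ("MB", "PAC", "PVC"):
            if self.u is None or not (0 < self.u <= 0.5) or self.T_ms is not None:
                raise ValueError(f"{self.kind} takes exactly u in (0, 0.5]")
        else:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass(frozen=True)
class PooledNoisySpec:
    """Recipe for the pooled noisy database: NSR split into four quarters."""

    fractions: dict = field(
        default_factory=lambda: {"original": 0.25, "MB": 0.25, "PAC": 0.25, "PVC": 0.25}
    )
    mb_pool: tuple = POOLED_MB_POOL
    ectopy_pool: tuple = ECTOPY_POOL
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions.values()) - 1.0) > 1e-12:
            raise ValueError("quarter fractions must sum to 1")


def _rng(seed) -> np.random.Generator:
    if seed is None or isinstance(seed, (int, np.integer)):
        return np.random.default_rng(seed)
    return seed  # a Generator (or any object with choice/uniform/integers)


def jitter_beats(beats: BeatSequence, T_ms: float, seed) -> BeatSequence:
    """Independent U[−T, T] shift on every beat time (T in ms)."""
    if T_ms <= 0:
        raise ValueError("T_ms must be positive")
    rng = _rng(seed)
    T = T_ms / 1000.0
    shifted = beats.times + rng.uniform(-T, T, size=len(beats))
    if np.any(np.diff(shifted) <= 0):
        raise PerturbationCollision(
            f"T = {T_ms} ms produced a non-positive interval "
            f"(record {beats.record_id!r}); jitter is not re-sorted"
        )
    return replace(beats, times=shifted)


def drop_beats(beats: BeatSequence, u: float, seed) -> BeatSequence:
    """Discard round(u·L) distinct beats, uniformly chosen."""
    if not 0 <= u <= 0.5:
        raise ValueError("u must lie in [0, 0.5]")
    L = len(beats)
    k = int(round(u * L))
    if k == 0:
        return beats
    if L - k < 2:
        raise InsufficientData(f"dropping {k} of {L} beats leaves < 2")
    rng = _rng(seed)
    drop = rng.choice(L, size=k, replace=False)
    keep = np.setdiff1d(np.arange(L), drop)
    return replace(beats, times=beats.times[keep])


def _eligible_gaps(times: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.diff(times) > 2 * MIN_ECTOPIC_MARGIN)


def insert_pac(beats: BeatSequence, u: float, seed) -> BeatSequence:
    """round(u·L) premature atrial beats; later beats shift forward."""
    rng = _rng(seed)
    times = beats.times.copy()
    n_events = int(round(u * len(beats)))
    for applied in range(n_events):
        gaps = _eligible_gaps(times)
        if gaps.size == 0:
            raise EligibilityExhausted(
                f"no gap > {2 * MIN_ECTOPIC_MARGIN:.1f} s left after "
                f"{applied} of {n_events} PAC insertions "
                f"(record {beats.record_id!r})",
                applied=applied,
            )
        i = int(rng.choice(gaps))
        b_i, b_next = times[i], times[i + 1]
        b_new = rng.uniform(b_i + MIN_ECTOPIC_MARGIN, b_next - MIN_ECTOPIC_MARGIN)
        shift = b_new - b_i
        times = np.concatenate([times[: i + 1], [b_new], times[i + 1 :] + shift])
    return replace(beats, times=times)


def insert_pvc(beats: BeatSequence, u: float, seed) -> BeatSequence:
    """round(u·L) premature ventricular beats; the next beat is deleted."""
    rng = _rng(seed)
    times = beats.times.copy()
    n_events = int(round(u * len(beats)))
    for applied in range(n_events):
        gaps = _eligible_gaps(times)
        # deleting the last beat would need a following beat to pause into;
        # the placement rule itself guarantees b̃ < b_{i+1} so any gap works
        if gaps.size == 0:
            raise EligibilityExhausted(
                f"no gap > {2 * MIN_ECTOPIC_MARGIN:.1f} s left after "
                f"{applied} of {n_events} PVC insertions "
                f"(record {beats.record_id!r})",
                applied=applied,
            )
        i = int(rng.choice(gaps))
        b_i, b_next = times[i], times[i + 1]
        b_new = rng.uniform(b_i + MIN_ECTOPIC_MARGIN, b_next - MIN_ECTOPIC_MARGIN)
        times = np.concatenate([times[: i + 1], [b_new], times[i + 2 :]])
        if len(times) < 2:
            raise InsufficientData("PVC left fewer than 2 beats")
    return replace(beats, times=times)


def apply_perturbation(beats: BeatSequence, spec: PerturbationSpec) -> BeatSequence:
    if spec.kind == "TU":
        return jitter_beats(beats, spec.T_ms, spec.seed)
    if spec.kind == "MB":
        return drop_beats(beats, spec.u, spec.seed)
    if spec.kind == "PAC":
        return insert_pac(beats, spec.u, spec.seed)
    if spec.kind == "PVC":
        return insert_pvc(beats, spec.u, spec.seed)
    raise ValueError(f"unknown kind {spec.kind!r}")


def build_pooled_noisy(
    nsr: list[BeatSequence],
    af: list[BeatSequence],
    spec: PooledNoisySpec | None = None,
) -> tuple[list[BeatSequence], list[dict]]:
    """Pooled noisy database: NSR quartered into original / MB / PAC / PVC.

    Each corrupted NSR sample draws its parameter uniformly from the spec's
    pool; any partition remainder stays in the "original" quarter.  AF samples
    pass through unperturbed here (TU/MB stress on AF belongs to the dedicated
    robustness sweeps).  Returns the sequences plus a per-record manifest
    (kind, parameter, seed) enabling exact replay.
    """
    if not nsr or not af:
        raise InsufficientData("both groups must be non-empty")
    spec = spec or PooledNoisySpec()
    rng = np.random.default_rng(spec.seed)

    order = rng.permutation(len(nsr))
    q = len(nsr) // 4
    quarters = {
        "MB": order[:q],
        "PAC": order[q : 2 * q],
        "PVC": order[2 * q : 3 * q],
        "original": order[3 * q :],  # remainder joins the original quarter
    }
    assignment = {}
    for kind, idxs in quarters.items():
        for i in idxs:
            assignment[int(i)] = kind

    out, manifest = [], []
    for i, beats in enumerate(nsr):
        kind = assignment[i]
        entry = {"record_id": beats.record_id, "label": beats.label, "kind": kind}
        if kind == "original":
            out.append(beats)
        else:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if kind == "MB":
                u = float(rng.choice(spec.mb_pool))
                out.append(drop_beats(beats, u, sub_seed))
            elif kind == "PAC":
                u = float(rng.choice(spec.ectopy_pool))
                out.append(insert_pac(beats, u, sub_seed))
            else:
                u = float(rng.choice(spec.ectopy_pool))
                out.append(insert_pvc(beats, u, sub_seed))
            entry.update({"u": u, "seed": sub_seed})
        manifest.append(entry)
    for beats in af:
        out.append(beats)
        manifest.append(
            {"record_id": beats.record_id, "label": beats.label, "kind": "original"}
        )
    return out, manifest
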