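"""Synthetic NSR and AF beat sequences.

The generator emulates the statistical structure the analysis relies on, not
ECG morphology.  Each 1-min series draws a per-series mean RR and a
per-series beat-to-beat SD from group-level distributions, then fills in the
beat-to-beat dynamics:

* **NSR** — a smooth rhythm: AR(1) fluctuations (lag-1 coefficient ≈ 0.95)
  mixed with a sinusoidal respiratory modulation (~0.25 Hz).  Group targets:
  mean RR 0.80 ± 0.15 s across series, within-series SD 0.04 ± 0.02 s.
* **AF** — an irregularly irregular rhythm: near-independent skewed (gamma)
  innovations.  Group targets: mean RR 0.61 ± 0.08 s, within-series SD
  0.12 ± 0.03 s.

The realized deviations of every series are standardized and rescaled so its
sample mean and sample SD equal the drawn per-series targets exactly; the
group-level spread of the per-series statistics is then governed directly by
the draw distributions.  Per-series SDs are drawn lognormal (matching the
target mean/SD in closed form) so they stay positive without truncation
distortion.  Physiological floors (0.3 s NSR, 0.25 s AF) are enforced by
rejection — a series whose rescaled tachogram dips below the floor is
redrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InsufficientData
from .rr_timeseries import BeatSequence

__all__ = [
    "RhythmModelParams",
    "NSR_DEFAULTS",
    "AF_DEFAULTS",
    "simulate_nsr",
    "simulate_af",
    "make_dataset",
]

RESP_FREQ_HZ = 0.25  # respiratory modulation of NSR
RESP_VARIANCE_SHARE = 0.3  # share of within-series variance carried by it
MAX_REJECTIONS = 200


@dataclass(frozen=True)
class RhythmModelParams:
    """Group-level generative parameters, all in seconds where dimensional."""

    mean_rr: float
    between_series_sd: float  # spread of per-series mean RR across series
    within_series_sd: float  # typical beat-to-beat SD inside one series
    within_sd_spread: float  # group-level spread of the per-series SD
    autocorr: float  # lag-1 coefficient of the beat-to-beat process
    duration_s: float = 60.0
    mean_bounds: tuple = (0.5, 1.2)  # truncation of the per-series mean draw
    rr_floor: float = 0.3

    def __post_init__(self):
        if not self.mean_rr > 3 * self.within_series_sd >= 0:
            raise ValueError("require mean_rr > 3 * within_series_sd >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.autocorr < 1:
            raise ValueError("autocorr must lie in [0, 1)")


NSR_DEFAULTS = RhythmModelParams(
    mean_rr=0.80,
    between_series_sd=0.15,
    within_series_sd=0.04,
    within_sd_spread=0.02,
    autocorr=0.95,
    duration_s=60.0,
    mean_bounds=(0.5, 1.2),
    rr_floor=0.30,
)

AF_DEFAULTS = RhythmModelParams(
    mean_rr=0.61,
    between_series_sd=0.08,
    within_series_sd=0.12,
    within_sd_spread=0.03,
    autocorr=0.10,
    duration_s=60.0,
    mean_bounds=(0.35, 0.9),
    rr_floor=0.25,
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(MAX_REJECTIONS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise InsufficientData("per-series mean draw kept falling outside bounds")


def _lognormal_sd(rng, mean, sd) -> float:
    """Positive draw with the given mean and SD (exact lognormal moments)."""
    if sd == 0 or mean == 0:
        return float(mean)
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(s2)))


def _assemble(deviations: np.ndarray, m: float, w: float, params, label, record_id, clip=False):
    """Rescale raw deviations to sample stats (m, w) and cumulate to beats.

    Returns None when the rescaled tachogram dips below the physiological
    floor, so the caller can redraw the *deviations only* — the per-series
    targets (m, w) are kept, which leaves the group-level statistics of the
    drawn targets unbiased.  With ``clip`` the rare stubborn series is
    floored instead of redrawn again.
    """
    z = deviations - deviations.mean()
    sd = z.std(ddof=1)
    rr = np.full_like(z, m) if (sd == 0 or w == 0) else m + w * z / sd
    if np.any(rr < params.rr_floor):
        if not clip:
            return None
        rr = np.maximum(rr, params.rr_floor)
    times = np.concatenate([[0.0], np.cumsum(rr)])
    keep = times <= params.duration_s
    times = times[keep]
    if len(times) < 2:
        raise InsufficientData(
            f"duration {params.duration_s} s holds fewer than one interval"
        )
    return BeatSequence(times=times, label=label, record_id=record_id)


def _n_beats(params, m) -> int:
    return int(math.ceil(params.duration_s / max(m, 1e-6))) + 8


def _nsr_deviations(rng, n, m, params):
    rho = params.autocorr
    innov = rng.normal(0.0, math.sqrt(max(1.0 - rho**2, 1e-12)), size=n)
    z = np.empty(n)
    z[0] = rng.normal()
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innov[i]
    if params.within_series_sd > 0:
        phase = rng.uniform(0, 2 * math.pi)
        t_approx = np.arange(n) * m
        resp = np.sqrt(2 * RESP_VARIANCE_SHARE) * np.sin(
            2 * math.pi * RESP_FREQ_HZ * t_approx + phase
        )
        z = math.sqrt(1 - RESP_VARIANCE_SHARE) * z + resp
    return z


def simulate_nsr(params: RhythmModelParams | None = None, seed=None, record_id: str = "") -> BeatSequence:
    """One NSR-like beat sequence: smooth AR(1) + respiratory modulation."""
    params = params or NSR_DEFAULTS
    rng = _rng(seed)
    m = _truncated_normal(
        rng, params.mean_rr, params.between_series_sd, *params.mean_bounds
    )
    w = _lognormal_sd(rng, params.within_series_sd, params.within_sd_spread)
    n = _n_beats(params, m)
    for _ in range(MAX_REJECTIONS):
        z = _nsr_deviations(rng, n, m, params)
        beats = _assemble(z, m, w, params, "NSR", record_id)
        if beats is not None:
            return beats
    return _assemble(z, m, w, params, "NSR", record_id, clip=True)


def _af_deviations(rng, n, params):
    # skewed marginal: gamma innovations shaped to the group's mean/SD ratio
    shape = max((params.mean_rr / max(params.within_series_sd, 1e-9)) ** 2, 1.0)
    g = rng.gamma(shape, 1.0, size=n)
    g = (g - shape) / math.sqrt(shape)  # standardized, skew 2/sqrt(shape)
    rho = params.autocorr
    if rho > 0:
        z = np.empty(n)
        z[0] = g[0]
        for i in range(1, n):
            z[i] = rho * z[i - 1] + math.sqrt(1 - rho**2) * g[i]
        return z
    return g


def simulate_af(params: RhythmModelParams | None = None, seed=None, record_id: str = "") -> BeatSequence:
    """One AF-like beat sequence: near-independent skewed innovations."""
    params = params or AF_DEFAULTS
    rng = _rng(seed)
    m = _truncated_normal(
        rng, params.mean_rr, params.between_series_sd, *params.mean_bounds
    )
    w = _lognormal_sd(rng, params.within_series_sd, params.within_sd_spread)
    n = _n_beats(params, m)
    for _ in range(MAX_REJECTIONS):
        z = _af_deviations(rng, n, params)
        beats = _assemble(z, m, w, params, "AF", record_id)
        if beats is not None:
            return beats
    return _assemble(z, m, w, params, "AF", record_id, clip=True)


def make_dataset(
    n_nsr: int,
    n_af: int,
    duration_s: float = 60.0,
    seed=None,
    nsr_params: RhythmModelParams | None = None,
    af_params: RhythmModelParams | None = None,
) -> list[BeatSequence]:
    """Independent labelled NSR + AF series, reproducible under the seed."""
    if n_nsr < 1 or n_af < 1:
        raise ValueError("need at least one series per group")
    rng = _rng(seed)
    nsr_p = replace(nsr_params or NSR_DEFAULTS, duration_s=duration_s)
    af_p = replace(af_params or AF_DEFAULTS, duration_s=duration_s)
    out = []
    for i in range(n_nsr):
        out.append(simulate_nsr(nsr_p, seed=rng, record_id=f"nsr-{i:04d}"))
    for i in range(n_af):
        out.append(simulate_af(af_p, seed=rng, record_id=f"af-{i:04d}"))
    return out
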