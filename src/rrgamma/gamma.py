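"""The γ separation metric between group ellipsoids.

Each rhythm group, in the space of the currently selected state variables, is
modelled by the 1-standard-deviation ellipsoid of its sample distribution:
center μ (per-feature mean) and shape Σ (unbiased sample covariance), whose
axes are the covariance eigenvectors.  For two groups the pairwise distance is
the normalized surface-to-surface algebraic gap along the mean–mean axis:

    u = (μ2 − μ1)/‖μ2 − μ1‖
    r_k = 1/sqrt(uᵀ Σ_k⁻¹ u)          (radius of ellipsoid k along u)
    d = (‖μ2 − μ1‖ − r1 − r2) / (r1 + r2)

d > 0 when the two surfaces do not overlap along that axis, d < 0 when they
do, and d = −1 exactly when the centers coincide.  In one dimension this
reduces to (|μ1−μ2| − (σ1+σ2))/(σ1+σ2).  For K groups the metric γ_M is the
sum of d over all unordered pairs, so γ ≥ −1 for K = 2.

γ is affine-invariant: applying one invertible linear map plus translation to
all groups' samples leaves every pairwise d unchanged, because both the gap
and the radii scale by the same factor along the mapped axis.

Variable selection is an exhaustive search: for each subset size n, every
n-combination of the candidate variables is scored by γ and the best kept.
Enumeration is exact by default; an optional per-size budget switches to a
flagged greedy-beam search for very large spaces.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGroups, InsufficientData, InsufficientGroups
from .features import FeatureMatrix, FeatureName

__all__ = [
    "GroupEllipsoid",
    "GammaResult",
    "SubsetRanking",
    "fit_ellipsoid",
    "pair_distance",
    "gamma_metric",
    "univariate_gamma",
    "exhaustive_subset_search",
]

RIDGE_EPS = 1e-10


@dataclass(frozen=True)
class GroupEllipsoid:
    """(μ, Σ, n) model of one group in the selected-variable space."""

    center: np.ndarray
    covariance: np.ndarray
    n: int
    group_id: str = ""

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        S = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "covariance", S)
        if S.shape != (c.size, c.size):
            raise ValueError(f"covariance {S.shape} incompatible with center dim {c.size}")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("covariance not symmetric")

    @property
    def dim(self) -> int:
        return self.center.size


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    pair_distances: dict  # (group_id1, group_id2) -> d
    subset: tuple = ()
    K: int = 2


@dataclass
class SubsetRanking:
    """Best variable subset per size, plus the overall winner."""

    best_per_size: dict  # size -> (tuple[FeatureName], gamma)
    global_best: tuple  # (tuple[FeatureName], gamma)
    mode: str = "exact"  # "exact" | "beam"
    excluded: tuple = ()  # features with zero variance in both groups
    seed: int | None = None
    input_digest: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "input_digest": self.input_digest,
                "excluded": [f.column for f in self.excluded],
                "best_per_size": {
                    str(n): {"subset": [f.column for f in sub], "gamma": g}
                    for n, (sub, g) in sorted(self.best_per_size.items())
                },
                "global_best": {
                    "subset": [f.column for f in self.global_best[0]],
                    "gamma": self.global_best[1],
                },
            },
            indent=2,
        )


def _ridge(S: np.ndarray) -> np.ndarray:
    scale = float(np.mean(np.diag(S)))
    if scale <= 0:
        scale = 1.0  # fully degenerate group: unit ridge keeps Σ invertible
    return S + RIDGE_EPS * scale * np.eye(S.shape[0])


def fit_ellipsoid(samples: np.ndarray, group_id: str = "") -> GroupEllipsoid:
    """Center = per-feature mean; Σ = unbiased sample covariance + tiny ridge."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D array (n_samples, n_features)")
    n = X.shape[0]
    if n < 2:
        raise InsufficientData(f"group {group_id!r} has {n} sample(s); need >= 2")
    center = X.mean(axis=0)
    dev = X - center
    S = dev.T @ dev / (n - 1)
    return GroupEllipsoid(center=center, covariance=_ridge(S), n=n, group_id=group_id)


def _axis_radius(S: np.ndarray, u: np.ndarray) -> float:
    """Radius of the 1-SD ellipsoid along unit direction u: 1/sqrt(uᵀΣ⁻¹u).

    A singular Σ describes a flattened ellipsoid: the radius is 0 when u
    leaves range(Σ), else the pseudo-inverse takes over.
    """
    try:
        q = float(u @ np.linalg.solve(S, u))
    except np.linalg.LinAlgError:
        Sp = np.linalg.pinv(S, hermitian=True)
        if np.linalg.norm(S @ (Sp @ u) - u) > 1e-8 * np.linalg.norm(u):
            return 0.0
        q = float(u @ Sp @ u)
        if q <= 0:
            return 0.0
    if q <= 0:
        return math.inf
    return 1.0 / math.sqrt(q)


def pair_distance(e1: GroupEllipsoid, e2: GroupEllipsoid) -> float:
    """Normalized surface-to-surface gap along the mean–mean axis."""
    if e1.dim != e2.dim:
        raise ValueError("ellipsoid dimension mismatch")
    delta = e2.center - e1.center
    gap = float(np.linalg.norm(delta))
    if gap == 0.0:
        # degenerate axis: any direction gives gap −(r1+r2) ⇒ d = −1,
        # unless both radii vanish too
        tr1 = float(np.trace(e1.covariance))
        tr2 = float(np.trace(e2.covariance))
        if tr1 == 0 and tr2 == 0:
            raise DegenerateGroups("coincident centers with zero extent")
        return -1.0
    u = delta / gap
    r1 = _axis_radius(e1.covariance, u)
    r2 = _axis_radius(e2.covariance, u)
    rsum = r1 + r2
    if rsum == 0.0:
        return math.inf
    if math.isinf(rsum):
        return -1.0
    return (gap - rsum) / rsum


def gamma_metric(groups: Sequence[GroupEllipsoid], subset: tuple = ()) -> GammaResult:
    """Sum of pairwise distances over all unordered group pairs."""
    if len(groups) < 2:
        raise InsufficientGroups(f"need >= 2 groups, got {len(groups)}")
    dims = {g.dim for g in groups}
    if len(dims) != 1:
        raise ValueError("groups live in different dimensions")
    pair_distances = {}
    total = 0.0
    for (i, g1), (j, g2) in itertools.combinations(enumerate(groups), 2):
        d = pair_distance(g1, g2)
        pair_distances[(g1.group_id or str(i), g2.group_id or str(j))] = d
        total += d
    return GammaResult(gamma=total, pair_distances=pair_distances, subset=tuple(subset), K=len(groups))


def univariate_gamma(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """1-D γ between two (mean, SD) summaries.

    This is the 1-D specialization of :func:`pair_distance`: the ellipsoids
    are segments [μ±σ] and the metric is the normalized gap between them.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    gap = abs(mu2 - mu1)
    rsum = sd1 + sd2
    if rsum == 0.0:
        if gap == 0.0:
            raise DegenerateGroups("identical point groups")
        return math.inf
    return (gap - rsum) / rsum


# ---------------------------------------------------------------------------
# subset search
# ---------------------------------------------------------------------------


def _group_summaries(features: FeatureMatrix):
    labels = sorted(set(features.labels))
    if len(labels) != 2:
        raise InsufficientGroups(f"subset search needs exactly 2 labels, got {labels}")
    out = []
    for lab in labels:
        X = features.group(lab)
        if X.shape[0] < 2:
            raise InsufficientData(f"group {lab!r} has {X.shape[0]} sample(s)")
        mu = X.mean(axis=0)
        dev = X - mu
        S = dev.T @ dev / (X.shape[0] - 1)
        out.append((lab, mu, S))
    return out


def _subset_gamma(idx: tuple, mu1, S1, mu2, S2) -> float:
    ix = np.asarray(idx)
    delta = mu2[ix] - mu1[ix]
    gap = float(np.linalg.norm(delta))
    if gap == 0.0:
        return -1.0
    u = delta / gap
    r = 0.0
    for S in (S1, S2):
        Ssub = _ridge(S[np.ix_(ix, ix)])
        r += _axis_radius(Ssub, u)
    if r == 0.0:
        return math.inf
    return (gap - r) / r


def exhaustive_subset_search(
    features: FeatureMatrix,
    sizes: Sequence[int] | None = None,
    exact_limit: int | None = None,
    beam_width: int = 64,
    seed: int | None = None,
) -> SubsetRanking:
    """Rank variable subsets by γ between the two labelled groups.

    For every requested size n the search scores all C(M, n) subsets and keeps
    the maximum; ties go to the lexicographically smallest subset in canonical
    feature order (mean 0..K then sd 0..K).  Candidate features with zero
    sample variance in *both* groups are excluded up front (γ along such an
    axis would be an artifact of the ridge) and reported in ``excluded``.

    ``exact_limit`` caps the number of subsets enumerated per size; beyond it
    a greedy beam search (width ``beam_width``) extends the best smaller
    subsets, and the result is flagged ``mode="beam"``.
    """
    names = features.feature_names
    (lab1, mu1, S1), (lab2, mu2, S2) = _group_summaries(features)

    keep, excluded = [], []
    for i, name in enumerate(names):
        if S1[i, i] == 0.0 and S2[i, i] == 0.0:
            excluded.append(name)
        else:
            keep.append(i)
    if not keep:
        raise InsufficientData("every candidate feature is constant in both groups")

    M = len(keep)
    if sizes is None:
        sizes = range(1, M + 1)
    sizes = sorted({int(n) for n in sizes})
    if any(n < 1 or n > M for n in sizes):
        raise ValueError(f"subset sizes must lie in 1..{M}")

    digest = hashlib.sha256(
        np.ascontiguousarray(features.values()).tobytes()
    ).hexdigest()[:16]

    best_per_size: dict = {}
    mode = "exact"
    prev_frontier: list[tuple] = []  # best subsets of the previous size, for beam

    def grow(frontier: list, target: int) -> list:
        """Beam step: extend subsets one feature at a time, pruning by γ."""
        current = frontier
        while (len(current[0]) if current else 0) < target:
            cands = {
                tuple(sorted(set(base) | {i}))
                for base in current
                for i in keep
                if i not in base
            }
            ranked = sorted(
                ((_subset_gamma(c, mu1, S1, mu2, S2), c) for c in cands),
                key=lambda t: (-t[0], t[1]),
            )
            current = [c for _, c in ranked[:beam_width]]
        return current

    for n in sizes:
        n_subsets = math.comb(M, n)
        if exact_limit is not None and n_subsets > exact_limit:
            mode = "beam"
            seedset = [idx for idx in prev_frontier if len(idx) < n] or [()]
            candidates = grow(seedset, n)
        else:
            candidates = itertools.combinations(keep, n)

        best_idx, best_g = None, -math.inf
        scored = []
        for idx in candidates:
            g = _subset_gamma(idx, mu1, S1, mu2, S2)
            if g > best_g:  # strict: first (lex-smallest) subset wins ties
                best_idx, best_g = idx, g
            if exact_limit is not None:
                scored.append((g, idx))
        if best_idx is None:
            continue
        best_per_size[n] = (tuple(names[i] for i in best_idx), best_g)
        if exact_limit is not None:
            scored.sort(key=lambda t: (-t[0], t[1]))
            prev_frontier = [idx for _, idx in scored[:beam_width]]

    if not best_per_size:
        raise InsufficientData("no evaluable subset size")
    global_best = max(
        ((sub, g) for n, (sub, g) in sorted(best_per_size.items())),
        key=lambda t: t[1],
    )
    return SubsetRanking(
        best_per_size=best_per_size,
        global_best=global_best,
        mode=mode,
        excluded=tuple(excluded),
        seed=seed,
        input_digest=digest,
    )
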