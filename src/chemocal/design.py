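"""Calibration designs and validation-set sampling.

The calibration set follows a multilevel multifactorial design: for two
components at five levels (coded -2..+2 over 5.0-25.0 ug/mL) this is the
full 5 x 5 factorial of 25 mixtures, each level appearing exactly five
times per factor.  Validation sets are drawn either by Latin hypercube
sampling (LHS: each of ``n_strata`` equal-width intervals per dimension
holds exactly one point, strata permuted independently per dimension) or
plain Monte Carlo (i.i.d. uniform), so the two strategies can be compared
under identical bounds and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "MixtureDesign",
    "SamplingPlan",
    "multilevel_design",
    "lhs_sample",
    "mc_sample",
    "coverage_report",
    "DEFAULT_LEVELS",
]

#: Default concentration levels (ug/mL) for the 5-level study design.
DEFAULT_LEVELS = (5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass(frozen=True)
class MixtureDesign:
    """Coded multilevel design and its decoded concentrations."""

    level_codes: np.ndarray      # n_runs x n_factors, integer codes
    level_values: tuple[float, ...]
    concentrations: np.ndarray   # n_runs x n_factors, ug/mL

    @property
    def n_runs(self) -> int:
        return self.level_codes.shape[0]

    @property
    def n_factors(self) -> int:
        return self.level_codes.shape[1]


def multilevel_design(
    n_levels: int = 5,
    n_factors: int = 2,
    level_values: tuple[float, ...] = DEFAULT_LEVELS,
) -> MixtureDesign:
    """Full multilevel multifactorial calibration design.

    For two factors this is the complete ``n_levels**2`` run set; at five
    levels it is the 25-mixture calibration design.  Codes are centered
    integers (five levels -> -2..+2) mapped in order onto *level_values*.
    """
    if n_factors != 2:
        raise ValueError(
            "only the two-component design is supported (n_factors must be 2)"
        )
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    level_values = tuple(float(v) for v in level_values)
    if len(level_values) != n_levels:
        raise ValueError(
            f"{len(level_values)} level values for {n_levels} levels"
        )
    if np.any(np.diff(level_values) <= 0):
        raise ValueError("level_values must be strictly increasing")
    # centered integer codes: 5 levels -> -2..2, 4 levels -> -2..1 (offset form)
    codes_1d = np.arange(n_levels) - (n_levels - 1) // 2
    codes = np.array(list(product(codes_1d, repeat=n_factors)), dtype=int)
    lookup = dict(zip(codes_1d, level_values))
    conc = np.vectorize(lookup.get)(codes).astype(float)
    return MixtureDesign(codes, level_values, conc)


@dataclass(frozen=True)
class SamplingPlan:
    """A validation point set with its generation bookkeeping."""

    method: str                       # "lhs" or "monte_carlo"
    n_points: int
    bounds: tuple[tuple[float, float], ...]
    points: np.ndarray                # n_points x n_dims, ug/mL
    seed: int
    n_strata: int | None = None       # lhs only

    @property
    def n_dims(self) -> int:
        return len(self.bounds)


def _check_bounds(bounds) -> tuple[tuple[float, float], ...]:
    out = []
    for d, (low, high) in enumerate(bounds):
        low, high = float(low), float(high)
        if not low < high:
            raise ValueError(f"dimension {d}: bounds ({low}, {high}) invalid")
        out.append((low, high))
    return tuple(out)


def lhs_sample(
    n_strata: int,
    n_dims: int = 2,
    bounds=(((5.0, 25.0),) * 2),
    seed: int = 0,
) -> SamplingPlan:
    """Latin hypercube sample: one point per stratum per dimension.

    Each dimension's range is split into ``n_strata`` equal-width intervals
    ("equal probability" under the uniform marginal); a point lands
    uniformly inside each interval and the interval order is permuted
    independently per dimension.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    bounds = _check_bounds(bounds)
    if len(bounds) != n_dims:
        raise ValueError(f"{len(bounds)} bounds for {n_dims} dimensions")
    rng = np.random.default_rng(seed)
    points = np.empty((n_strata, n_dims))
    for d, (low, high) in enumerate(bounds):
        perm = rng.permutation(n_strata)
        jitter = rng.random(n_strata)
        points[:, d] = low + (perm + jitter) / n_strata * (high - low)
    return SamplingPlan("lhs", n_strata, bounds, points, seed, n_strata=n_strata)


def mc_sample(
    n_points: int,
    n_dims: int = 2,
    bounds=(((5.0, 25.0),) * 2),
    seed: int = 0,
) -> SamplingPlan:
    """Monte Carlo sample: i.i.d. uniform points inside the bounds."""
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    bounds = _check_bounds(bounds)
    if len(bounds) != n_dims:
        raise ValueError(f"{len(bounds)} bounds for {n_dims} dimensions")
    rng = np.random.default_rng(seed)
    u = rng.random((n_points, n_dims))
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    points = lows + u * (highs - lows)
    return SamplingPlan("monte_carlo", n_points, bounds, points, seed)


@dataclass(frozen=True)
class CoverageReport:
    """Per-dimension bin occupancy and the minimum pairwise distance."""

    occupancy: np.ndarray        # n_dims x n_bins counts
    n_bins: int
    min_pairwise_distance: float
    n_empty_bins: np.ndarray = field(default=None)  # per dimension

    def __post_init__(self):
        object.__setattr__(
            self, "n_empty_bins", (self.occupancy == 0).sum(axis=1)
        )


def coverage_report(plan: SamplingPlan, n_bins: int) -> CoverageReport:
    """Space-coverage diagnostics of a sampling plan.

    Counts points per equal-width bin along every dimension (bins span the
    plan's bounds, right-open except the last) and reports the minimum
    pairwise Euclidean distance between points.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if plan.n_points == 0:
        raise ValueError("cannot report coverage of an empty plan")
    occ = np.empty((plan.n_dims, n_bins), dtype=int)
    for d, (low, high) in enumerate(plan.bounds):
        idx = np.floor((plan.points[:, d] - low) / (high - low) * n_bins)
        idx = np.clip(idx.astype(int), 0, n_bins - 1)
        occ[d] = np.bincount(idx, minlength=n_bins)
    if plan.n_points >= 2:
        min_dist = float(pdist(plan.points).min())
    else:
        min_dist = float("inf")
    return CoverageReport(occ, n_bins, min_dist)
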