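"""Velocity estimation and condition comparison.

Migration velocity for one technical replicate is the ordinary
least-squares slope of normalized area (percent of the t0 area) versus
time; a condition's velocity is the median slope over its replicates.
Conditions are compared pairwise with a Mann–Whitney U test on the
replicate slope lists — exact by enumeration at the small sample sizes
typical of plate assays, tie-corrected normal approximation otherwise —
with Bonferroni or Benjamini–Hochberg control over the set of pairs.

Slopes are reported signed: negative for a shrinking cell-free area
(wound-healing orientation), positive for a growing covered area; the
condition's ``assay_kind`` tells the consumer how to read the sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .plugins import register_plugin, registry
from .preprocessing import NormalizedSeries

# ---------------------------------------------------------------------------
# Replicate-level regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicateFit:
    well_name: str
    slope: float  # % area per time unit
    intercept: float  # %
    r_squared: float
    n_points: int


def fit_replicate(ns: NormalizedSeries) -> ReplicateFit:
    """OLS of normalized area on time.

    R² = 1 − SSres/SStot; when the response has zero variance the ratio is
    undefined and R² is 1 for a perfect (flat) fit, 0 otherwise.
    """
    t = np.asarray(ns.time, dtype=float)
    y = np.asarray(ns.normalized, dtype=float)
    n = len(t)
    if n < 3:
        raise ValidationError(f"regression needs >= 3 points, got {n}")
    st = float(np.sum((t - t.mean()) ** 2))
    if st == 0:
        raise ValidationError("zero variance in time")
    slope = float(np.sum((t - t.mean()) * (y - y.mean())) / st)
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if np.allclose(resid, 0.0) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    return ReplicateFit(
        well_name=ns.well.name,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=n,
    )


@dataclass(frozen=True)
class ConditionResult:
    condition: str
    fits: tuple[ReplicateFit, ...]
    median_velocity: float

    @property
    def slopes(self) -> list[float]:
        return [f.slope for f in self.fits]


def condition_velocity(condition: str, fits: list[ReplicateFit]) -> ConditionResult:
    """Median replicate slope (even count: mean of the central pair)."""
    if not fits:
        raise ValidationError(f"condition {condition!r} has no replicate fits")
    return ConditionResult(
        condition=condition,
        fits=tuple(fits),
        median_velocity=float(np.median([f.slope for f in fits])),
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

#: largest pooled sample for which 'auto' mode enumerates exactly
EXACT_AUTO_LIMIT = 12


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # midrank, 1-based
        i = j + 1
    return ranks


def _u_from_ranks(ranks: np.ndarray, n_a: int) -> float:
    r_a = float(np.sum(ranks[:n_a]))
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(
    a, b, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of the first sample, p).

    mode='exact' enumerates all C(n_a+n_b, n_a) group assignments;
    'normal_approx' uses the tie-corrected Gaussian with continuity
    correction; 'auto' picks exact when n_a+n_b <= 12 and the pooled data
    are tie-free.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    has_ties = len(np.unique(pooled)) < n
    ranks = _midranks(pooled)
    u_a = _u_from_ranks(ranks, n_a)
    u_b = n_a * n_b - u_a

    if mode == "exact" or (mode == "auto" and n <= EXACT_AUTO_LIMIT and not has_ties):
        u_min = min(u_a, u_b)
        count = 0
        total = 0
        for idx in combinations(range(n), n_a):
            total += 1
            u = float(np.sum(ranks[list(idx)])) - n_a * (n_a + 1) / 2.0
            if u <= u_min + 1e-12:
                count += 1
        p = min(1.0, 2.0 * count / total)
        return u_a, p

    mu = n_a * n_b / 2.0
    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_a, 1.0  # all observations identical
    diff = u_a - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * 0.5 * math.erfc(max(z, 0.0) / math.sqrt(2.0)))
    return u_a, p


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------


def _bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, len(p) * p)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # step-up: q_(i) = min over j >= i of m*p_(j)/j
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(1.0, q_sorted)
    return q


ADJUSTMENTS = {"bonferroni": _bonferroni, "benjamini_hochberg": _benjamini_hochberg}


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Adjust raw p-values for multiplicity; results stay in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("need a non-empty 1-D vector of p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    try:
        fn = ADJUSTMENTS[method]
    except KeyError:
        raise ValidationError(
            f"unknown correction {method!r}; available {sorted(ADJUSTMENTS)}"
        ) from None
    return fn(p)


# ---------------------------------------------------------------------------
# Pairwise condition comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseComparison:
    condition_a: str
    condition_b: str
    u_statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    significant: bool


def compare_conditions(
    results: list[ConditionResult],
    selection: list[str] | None = None,
    method: str = "benjamini_hochberg",
    alpha: float = 0.05,
    test: str = "mann_whitney",
    mode: str = "auto",
) -> list[PairwiseComparison]:
    """One two-sample test per unordered pair of selected conditions.

    The correction multiplicity m is the number of pairs actually tested,
    C(k, 2) for k selected conditions.
    """
    by_name = {r.condition: r for r in results}
    if selection is None:
        selection = [r.condition for r in results]
    missing = [s for s in selection if s not in by_name]
    if missing:
        raise LookupError(f"unknown condition name(s): {missing}")
    if len(selection) < 2:
        raise ValidationError("need at least 2 conditions to compare")
    test_fn = registry.get("statistical_test", test)
    pairs = list(combinations(selection, 2))
    raws, us = [], []
    for ca, cb in pairs:
        u, p = test_fn(by_name[ca].slopes, by_name[cb].slopes, mode=mode)
        us.append(u)
        raws.append(p)
    adj = adjust_pvalues(np.array(raws), method=method)
    return [
        PairwiseComparison(
            condition_a=ca,
            condition_b=cb,
            u_statistic=u,
            p_raw=p,
            p_adjusted=float(q),
            method=method,
            significant=bool(q <= alpha),
        )
        for (ca, cb), u, p, q in zip(pairs, us, raws, adj)
    ]


# default plugin wiring
registry.register("statistical_test", "mann_whitney", mann_whitney_u)
registry.register("correction_method", "bonferroni", _bonferroni)
registry.register("correction_method", "benjamini_hochberg", _benjamini_hochberg)


__all__ = [
    "ReplicateFit",
    "ConditionResult",
    "PairwiseComparison",
    "fit_replicate",
    "condition_velocity",
    "mann_whitney_u",
    "adjust_pvalues",
    "compare_conditions",
    "register_plugin",
    "EXACT_AUTO_LIMIT",
]
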