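"""Two-stage quality control.

Stage one screens individual time steps: per-step changes of the normalized
area are pooled per condition, a kernel density estimate is fitted over
them, and a step is flagged as an artifact when its delta both runs against
the expected trend (cell-free area growing in a wound-healing assay) and
falls outside the central 1−α probability mass of that density.  Such steps
are typically segmentation or imaging glitches, and the suggested
correction replaces the offending point by time-weighted linear
interpolation between its neighbours (terminal points are dropped).

Stage two screens whole technical replicates: pairwise Euclidean distances
between normalized trajectories on their shared time grid, with a replicate
flagged when its mean distance to the others exceeds
median + k·MAD of the per-replicate means.

Every flag carries a stable identifier and is resolved to an explicit
accept/reject decision — from a decision file or a blanket policy — before
analysis proceeds; nothing is corrected or excluded silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    GridError,
    ResolutionError,
    StateError,
    ValidationError,
)
from .plugins import registry
from .preprocessing import NormalizedSeries, against_trend

# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------


def _gaussian_kernel(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)


def _epanechnikov_kernel(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


KERNELS = {"gaussian": _gaussian_kernel, "epanechnikov": _epanechnikov_kernel}


@dataclass
class KernelDensity:
    """A fitted KDE: density(x) = (1/(n·h)) Σ K((x − xᵢ)/h)."""

    points: np.ndarray
    bandwidth: float
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.bandwidth <= 0:
            raise ValidationError("bandwidth must be positive")
        if self.kernel not in KERNELS:
            raise ValidationError(f"unknown kernel {self.kernel!r}")

    def evaluate(self, x) -> np.ndarray | float:
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        u = (xv[:, None] - self.points[None, :]) / self.bandwidth
        dens = KERNELS[self.kernel](u).sum(axis=1) / (len(self.points) * self.bandwidth)
        return float(dens[0]) if np.isscalar(x) or np.ndim(x) == 0 else dens

    def _grid(self, n: int = 4001, pad: float = 8.0) -> np.ndarray:
        lo = self.points.min() - pad * self.bandwidth
        hi = self.points.max() + pad * self.bandwidth
        return np.linspace(lo, hi, n)

    def central_interval(self, alpha: float = 0.05) -> tuple[float, float]:
        """(lo, hi) bounds of the central 1−α probability mass, by quadrature."""
        if not 0 < alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        grid = self._grid()
        dens = self.evaluate(grid)
        cdf = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))]
        )
        cdf /= cdf[-1]  # guard the ~1e-6 quadrature loss in the far tails
        lo = float(np.interp(alpha / 2.0, cdf, grid))
        hi = float(np.interp(1.0 - alpha / 2.0, cdf, grid))
        return lo, hi


def silverman_bandwidth(points: np.ndarray) -> float:
    """h = 0.9·min(sd, IQR/1.34)·n^(−1/5) (rule-of-thumb for a Gaussian kernel)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    sd = float(np.std(pts, ddof=1))
    q75, q25 = np.percentile(pts, [75, 25])
    iqr = float(q75 - q25)
    return 0.9 * min(sd, iqr / 1.34) * n ** (-0.2)


def fit_kde(
    deltas,
    kernel: str = "gaussian",
    bandwidth: float | str = "auto",
) -> KernelDensity:
    """Fit a KDE over per-step deltas; ``bandwidth='auto'`` uses Silverman."""
    pts = np.asarray(deltas, dtype=float)
    if pts.ndim != 1 or len(pts) < 2:
        raise ValidationError("KDE needs at least 2 delta values")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("KDE input must be finite")
    if bandwidth == "auto":
        h = silverman_bandwidth(pts)
        if h <= 0:
            h = 1e-3 * max(1.0, abs(float(np.mean(pts))))
            warnings.warn(
                "zero spread in deltas; falling back to a nominal bandwidth",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        h = float(bandwidth)
    return KernelDensity(points=pts, bandwidth=h, kernel=kernel)


# ---------------------------------------------------------------------------
# Step-artifact detection and correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactPolicy:
    """How step artifacts are judged.

    alpha: tail mass outside which a delta counts as extreme (two-sided
    central-interval construction; the against-trend side is the one used).
    require_against_trend: couple extremity with direction (the default);
    switching it off flags extreme steps in either direction.
    """

    alpha: float = 0.05
    require_against_trend: bool = True


@dataclass(frozen=True)
class StepArtifact:
    well_name: str
    source_label: str
    step_index: int
    delta_value: float
    density_at_delta: float
    reason: str  # low_density_tail | against_trend_excess

    @property
    def flag_id(self) -> str:
        return f"step:{self.well_name}:{self.source_label}:{self.step_index}"


def detect_step_artifacts(
    ns: NormalizedSeries,
    kde: KernelDensity,
    policy: ArtifactPolicy = ArtifactPolicy(),
) -> list[StepArtifact]:
    """Flag steps that are both against-trend and outside the KDE central mass.

    ``kde`` is normally fitted on the pooled deltas of the replicate's whole
    condition, which stabilizes the reference density at the 3–6 replicates
    typical of plate assays.
    """
    if kde is None:
        raise StateError("KDE not fitted")
    if ns.expected_trend is None:
        raise StateError("series not oriented; call preprocessing.orient() first")
    lo, hi = kde.central_interval(policy.alpha)
    deltas = ns.deltas
    mask_dir = against_trend(ns)
    out: list[StepArtifact] = []
    for i, d in enumerate(deltas):
        extreme_hi = d > hi
        extreme_lo = d < lo
        if policy.require_against_trend:
            if not mask_dir[i]:
                continue
            # against-trend side: upper tail for a decreasing assay,
            # lower tail for an increasing one
            hit = extreme_hi if ns.expected_trend == "decreasing" else extreme_lo
            reason = "against_trend_excess"
        else:
            hit = extreme_hi or extreme_lo
            reason = "low_density_tail"
        if hit:
            out.append(
                StepArtifact(
                    well_name=ns.well.name,
                    source_label=ns.source_label,
                    step_index=i,
                    delta_value=float(d),
                    density_at_delta=float(kde.evaluate(float(d))),
                    reason=reason,
                )
            )
    return sorted(out, key=lambda a: a.step_index)


def correct_artifact(ns: NormalizedSeries, artifact: StepArtifact) -> NormalizedSeries:
    """Repair a flagged step; the original series stays on ``ns.base``.

    The point terminating the flagged step is replaced by time-weighted
    linear interpolation between its neighbours; if the step is terminal the
    point is dropped instead.  Correcting the same step twice is a warned
    no-op.
    """
    i = artifact.step_index
    n = len(ns.normalized)
    if not 0 <= i < n - 1:
        raise ValidationError(f"step index {i} out of range for {n}-point series")
    if i in ns.corrected_steps:
        warnings.warn(
            f"step {i} of {ns.well.name}/{ns.source_label} already corrected",
            RuntimeWarning,
            stacklevel=2,
        )
        return ns
    values = ns.normalized.copy()
    times = ns.time.copy()
    if i == n - 2:  # terminal step: drop the last point
        values = values[:-1]
        times = times[:-1]
    else:
        t0, t1, t2 = times[i], times[i + 1], times[i + 2]
        v0, v2 = values[i], values[i + 2]
        values[i + 1] = v0 + (v2 - v0) * (t1 - t0) / (t2 - t0)
    return replace(
        ns,
        time=times,
        normalized=values,
        corrected_steps=ns.corrected_steps | {i},
    )


# ---------------------------------------------------------------------------
# Replicate screening by trajectory distance
# ---------------------------------------------------------------------------


def _euclidean(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _manhattan(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.abs(x - y)))


@dataclass
class ReplicateDistanceReport:
    condition: str
    replicate_ids: list[str]
    distance_matrix: np.ndarray
    mean_distance: np.ndarray
    flagged: list[str]

    def flag_ids(self) -> list[str]:
        return [f"replicate:{self.condition}:{rid}" for rid in self.flagged]


def shared_time_grid(series: list[NormalizedSeries], rel_tol: float = 1e-9):
    """Indices into each series for time points present in all of them.

    Matching is exact up to ``rel_tol`` relative tolerance; no interpolation
    is performed, so no data is invented.
    """
    ref = series[0].time
    index_lists: list[list[int]] = [[] for _ in series]
    for j, t in enumerate(ref):
        hit = [j]
        for s in series[1:]:
            scale = max(abs(t), 1.0)
            matches = np.nonzero(np.abs(s.time - t) <= rel_tol * scale)[0]
            if len(matches) == 0:
                break
            hit.append(int(matches[0]))
        else:
            for lst, idx in zip(index_lists, hit):
                lst.append(idx)
    return [np.asarray(lst, dtype=int) for lst in index_lists]


def replicate_distances(
    condition_series: list[NormalizedSeries],
    metric: str = "euclidean",
    k_mad: float = 3.0,
    condition_name: str = "",
) -> ReplicateDistanceReport:
    """Screen technical replicates by trajectory distance.

    A replicate is flagged when its mean distance to the other replicates
    exceeds median + k·MAD of the per-replicate mean distances (robust, so a
    single outlier cannot mask itself).
    """
    m = len(condition_series)
    if m < 2:
        raise ValidationError("replicate screening needs at least 2 replicates")
    idx = shared_time_grid(condition_series)
    n_shared = len(idx[0])
    if n_shared < 3:
        raise GridError(
            f"only {n_shared} shared time points across replicates; need >= 3"
        )
    dist_fn = registry.get("distance_metric", metric)
    mat = np.zeros((m, m))
    vals = [s.normalized[ix] for s, ix in zip(condition_series, idx)]
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = dist_fn(vals[i], vals[j])
    mean_d = mat.sum(axis=1) / (m - 1)
    med = float(np.median(mean_d))
    # normal-consistent MAD (x1.4826) so k_mad is in sigma-equivalents
    mad = 1.4826 * float(np.median(np.abs(mean_d - med)))
    cutoff = med + k_mad * mad
    ids = [s.well.name for s in condition_series]
    flagged = [ids[i] for i in range(m) if mean_d[i] > cutoff]
    return ReplicateDistanceReport(
        condition=condition_name,
        replicate_ids=ids,
        distance_matrix=mat,
        mean_distance=mean_d,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Decision resolution
# ---------------------------------------------------------------------------

ACTIONS = ("accept", "reject")
POLICIES = ("accept_all", "reject_all", "ask")


@dataclass(frozen=True)
class QCDecision:
    flag_id: str
    action: str  # accept = apply the suggested correction / exclusion
    provenance: str  # config_policy | decision_file


def read_decision_file(path: str | Path) -> dict[str, str]:
    """Parse a TSV decision file with columns flag_id, action."""
    decisions: dict[str, str] = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ACTIONS:
            raise ValidationError(
                f"{path}:{lineno}: expected 'flag_id<TAB>accept|reject'"
            )
        decisions[parts[0]] = parts[1]
    return decisions


def resolve_decisions(
    flag_ids: list[str],
    policy: str = "accept_all",
    decisions: dict[str, str] | None = None,
) -> list[QCDecision]:
    """One explicit decision per flag; file entries override the policy.

    Under ``ask`` every flag must appear in the decision file; unresolved
    flags raise :class:`ResolutionError` listing them.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}; expected {POLICIES}")
    decisions = decisions or {}
    unknown = sorted(set(decisions) - set(flag_ids))
    if unknown:
        raise ValidationError(f"decisions for unknown flags: {unknown}")
    out: list[QCDecision] = []
    unresolved: list[str] = []
    for fid in flag_ids:
        if fid in decisions:
            out.append(QCDecision(fid, decisions[fid], "decision_file"))
        elif policy == "accept_all":
            out.append(QCDecision(fid, "accept", "config_policy"))
        elif policy == "reject_all":
            out.append(QCDecision(fid, "reject", "config_policy"))
        else:
            unresolved.append(fid)
    if unresolved:
        raise ResolutionError(f"unresolved QC flags under policy 'ask': {unresolved}")
    return out


# default plugin wiring
registry.register("distance_metric", "euclidean", _euclidean)
registry.register("distance_metric", "manhattan", _manhattan)
registry.register("kde_kernel", "gaussian", _gaussian_kernel)
registry.register("kde_kernel", "epanechnikov", _epanechnikov_kernel)
registry.register("outlier_rule", "central_mass", detect_step_artifacts)
registry.register("outlier_rule", "median_mad", replicate_distances)


__all__ = [
    "KernelDensity",
    "silverman_bandwidth",
    "fit_kde",
    "ArtifactPolicy",
    "StepArtifact",
    "detect_step_artifacts",
    "correct_artifact",
    "ReplicateDistanceReport",
    "shared_time_grid",
    "replicate_distances",
    "QCDecision",
    "read_decision_file",
    "resolve_decisions",
]
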