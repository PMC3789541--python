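"""Normalization of area trajectories.

Raw areas are expressed as a percentage of the area at time zero, so every
replicate starts at 100 % and trajectories are comparable across wells,
plates and microscopes regardless of absolute wound size.  Per-step changes
of the normalized signal (the "deltas") feed the quality-control stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import TimeSeries
from .errors import ValidationError

#: Normalized values are percentages of the t0 area.
T0_PERCENT = 100.0

#: expected trend of the *normalized area* per assay kind
EXPECTED_TREND = {"open_area": "decreasing", "covered_area": "increasing"}


@dataclass
class NormalizedSeries:
    """A trajectory in percent-of-t0 units plus its per-step increments.

    ``base`` keeps the raw series untouched (QC corrections are
    non-destructive); ``expected_trend`` is set by :func:`orient` and tells
    QC which delta sign counts as an artifact direction.
    ``corrected_steps`` records step indices already repaired.
    """

    base: TimeSeries
    time: np.ndarray
    normalized: np.ndarray
    expected_trend: str | None = None
    corrected_steps: frozenset[int] = field(default_factory=frozenset)

    @property
    def deltas(self) -> np.ndarray:
        return np.diff(self.normalized)

    @property
    def well(self):
        return self.base.well

    @property
    def source_label(self) -> str:
        return self.base.source_label


def normalize(ts: TimeSeries) -> NormalizedSeries:
    """Scale the trajectory so the first point equals 100 exactly."""
    a0 = ts.area[0]
    if a0 <= 0:
        raise ValidationError("area at time 0 must be positive")
    normalized = T0_PERCENT * ts.area / a0
    normalized[0] = T0_PERCENT  # exact by contract, immune to rounding
    return NormalizedSeries(base=ts, time=ts.time.copy(), normalized=normalized)


def orient(ns: NormalizedSeries, assay_kind: str) -> NormalizedSeries:
    """Record the expected trend for the assay kind.

    Values are never sign-flipped — slopes stay physically interpretable in
    both assay kinds — only the direction that counts as "against trend"
    (area growing in a wound-healing assay, shrinking in an exclusion-zone
    assay) is annotated for the artifact detector.
    """
    try:
        trend = EXPECTED_TREND[assay_kind]
    except KeyError:
        raise ValidationError(
            f"unknown assay_kind {assay_kind!r}; expected one of "
            f"{sorted(EXPECTED_TREND)}"
        ) from None
    return replace(ns, expected_trend=trend)


def against_trend(ns: NormalizedSeries) -> np.ndarray:
    """Boolean mask over deltas that run against the expected trend."""
    if ns.expected_trend is None:
        raise ValidationError("series not oriented; call orient() first")
    d = ns.deltas
    return d > 0 if ns.expected_trend == "decreasing" else d < 0


__all__ = [
    "T0_PERCENT",
    "EXPECTED_TREND",
    "NormalizedSeries",
    "normalize",
    "orient",
    "against_trend",
]
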