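"""Time dispersion analysis of features (TDAF).

Given the per-minute feature series of every replicate plant in a cohort,
TDAF summarises each minute with the order statistics across replicates —
minimum, first quartile, median, third quartile, maximum — kept in temporal
order.  Plots show the median trace with min-max shading; the interquartile
range is emitted alongside for narrower dispersion displays.

Quartiles use linear interpolation between order statistics (the common
default of scientific numeric stacks), so cross-language reimplementations
agree exactly.

Phase comparison pools each phase's per-minute medians into a single phase
median and reports the after/before ratio.  A step-onset estimate — the
first after-phase minute from which the per-minute median stays above the
before-phase pooled third quartile for a configurable run of consecutive
minutes — is a pragmatic detector for sustained shifts, not an inferential
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CohortMismatchError
from .spectral import FeatureSeries

__all__ = ["TDAFSummary", "PhaseComparison", "tdaf_aggregate", "compare_phases"]


@dataclass
class TDAFSummary:
    """Per-minute dispersion summary of one feature across a cohort.

    All arrays are indexed by minute; ``n`` is the number of replicates
    contributing (constant across minutes within a phase).
    """

    feature_name: str
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n: int
    units: str = ""
    treatment: str = "unknown"
    phase: str = "before"

    def __post_init__(self) -> None:
        for name in ("median", "q1", "q3", "min", "max"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {
            self.median.size,
            self.q1.size,
            self.q3.size,
            self.min.size,
            self.max.size,
        }
        if len(lengths) != 1 or self.median.size == 0:
            raise CohortMismatchError("summary arrays must share a non-zero length")
        ok = (
            np.all(self.min <= self.q1 + 1e-12)
            and np.all(self.q1 <= self.median + 1e-12)
            and np.all(self.median <= self.q3 + 1e-12)
            and np.all(self.q3 <= self.max + 1e-12)
        )
        if not ok:
            raise CohortMismatchError(
                f"{self.feature_name}: order statistics out of order"
            )

    @property
    def minute_index(self) -> np.ndarray:
        return np.arange(self.median.size)

    def __len__(self) -> int:
        return self.median.size


@dataclass
class PhaseComparison:
    """Before/after contrast of one feature's pooled phase medians."""

    feature_name: str
    median_before: float
    median_after: float
    after_before_ratio: float
    onset_minute_estimate: int | None
    band: str | None = None
    treatment: str = "unknown"
    params: dict = field(default_factory=dict)


def tdaf_aggregate(series: list[FeatureSeries]) -> TDAFSummary:
    """Aggregate replicate feature series into per-minute order statistics.

    All series must share feature name and length (minute alignment).  The
    result is permutation-invariant in the replicate order.
    """
    if not series:
        raise CohortMismatchError("no feature series to aggregate")
    names = {s.feature_name for s in series}
    if len(names) > 1:
        raise CohortMismatchError(f"mixed features in one aggregate: {sorted(names)}")
    lengths = {len(s) for s in series}
    if len(lengths) > 1:
        raise CohortMismatchError(
            f"feature series of unequal length: {sorted(lengths)}"
        )
    phases = {s.phase for s in series}
    values = np.vstack([s.values for s in series])  # replicates x minutes
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], axis=0, method="linear")
    return TDAFSummary(
        feature_name=series[0].feature_name,
        median=med,
        q1=q1,
        q3=q3,
        min=values.min(axis=0),
        max=values.max(axis=0),
        n=values.shape[0],
        units=series[0].units,
        treatment=series[0].treatment,
        phase=phases.pop() if len(phases) == 1 else "mixed",
    )


def _pooled(values: np.ndarray) -> float:
    return float(np.median(values))


def _onset_estimate(
    after_median: np.ndarray, threshold: float, min_run: int
) -> int | None:
    """First minute from which the median exceeds *threshold* for at least
    *min_run* consecutive minutes; ``None`` if no such run exists."""
    above = after_median > threshold
    for start in range(above.size - min_run + 1):
        if above[start : start + min_run].all():
            return start
    return None


def compare_phases(
    before: TDAFSummary, after: TDAFSummary, min_run: int = 5
) -> PhaseComparison:
    """Contrast two phases of one feature.

    Pooled phase medians are the medians of the per-minute medians; the
    ratio is after/before (NaN when the before median is not positive).
    The onset estimate is the first after-phase minute from which the
    per-minute median exceeds the before phase's pooled q3 for at least
    ``min_run`` consecutive minutes.
    """
    if before.feature_name != after.feature_name:
        raise CohortMismatchError(
            f"phase mismatch: {before.feature_name!r} vs {after.feature_name!r}"
        )
    med_b = _pooled(before.median)
    med_a = _pooled(after.median)
    ratio = med_a / med_b if med_b > 0 else float("nan")
    threshold = _pooled(before.q3)
    onset = _onset_estimate(after.median, threshold, min_run)
    name = before.feature_name
    band = name.split(":", 1)[1] if name.startswith("abp:") else None
    return PhaseComparison(
        feature_name=name,
        median_before=med_b,
        median_after=med_a,
        after_before_ratio=ratio,
        onset_minute_estimate=onset,
        band=band,
        treatment=before.treatment,
        params={"min_run": min_run, "threshold": threshold},
    )
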