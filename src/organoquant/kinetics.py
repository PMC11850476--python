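"""Population readouts: size bins, per-frame aggregates, normalized series.

Five size categories -- Tiny, Small, Medium, Large, Huge -- are bounded at
four percentile ranks (default 20/40/60/80) of the pooled organoid areas of
a condition, so with distinct areas each bin holds about a fifth of the
population.  Thresholds are computed once over a declared scope and then
frozen, keeping a given physical size in the same bin across the whole time
course; intervals are half-open, right-closed (a tie at a threshold falls
into the lower bin).

Per-frame aggregates and their ratios to the first time point ("normalized
to initial time") are the kinetic readouts: organoid count, total and mean
area, mean eccentricity, healthy/unhealthy counts and per-bin occupancy.
Because whole regions rather than individual organoids are followed, two
organoids fusing is observable only as its region-level signature: the count
drops while the total area is (approximately) retained.  A count drop with a
large simultaneous area loss is death/disintegration, not a merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InsufficientDataError, NormalizationError
from .phenotyping import OrganoidRecord

__all__ = [
    "SIZE_BINS",
    "BinThresholds",
    "FrameSummary",
    "WellSeries",
    "compute_bin_thresholds",
    "assign_size_bin",
    "summarize_frame",
    "normalize_series",
    "detect_merge_candidates",
    "dose_response_table",
    "NORMALIZED_METRICS",
]

SIZE_BINS = ("Tiny", "Small", "Medium", "Large", "Huge")

#: metric names exported as baseline-normalized series
NORMALIZED_METRICS = (
    "count",
    "total_area",
    "mean_area",
    "mean_eccentricity",
    "healthy_count",
    "unhealthy_count",
) + tuple(f"bin_{name}" for name in SIZE_BINS)


@dataclass(frozen=True)
class BinThresholds:
    """Frozen size-bin boundaries (areas at four percentile ranks)."""

    q20: float
    q40: float
    q60: float
    q80: float
    percentiles: tuple[float, float, float, float] = (20.0, 40.0, 60.0, 80.0)
    source_scope: str = ""

    def __post_init__(self) -> None:
        if not (self.q20 <= self.q40 <= self.q60 <= self.q80):
            raise ValueError("bin thresholds must be non-decreasing")

    @property
    def values(self) -> tuple[float, float, float, float]:
        return (self.q20, self.q40, self.q60, self.q80)


@dataclass(frozen=True)
class FrameSummary:
    """Aggregates of all organoids of one well at one time point.

    ``mean_area``/``mean_eccentricity`` are ``None`` (not 0) when the frame
    holds no organoids.
    """

    time_h: float
    count: int
    total_area: float
    mean_area: Optional[float]
    mean_eccentricity: Optional[float]
    healthy_count: int
    unhealthy_count: int
    bin_counts: dict[str, int]


@dataclass
class WellSeries:
    """Time-ordered summaries of one well plus its normalized series."""

    well_id: str
    condition_id: str
    summaries: list[FrameSummary]
    normalized: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [s.time_h for s in self.summaries]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConsistencyError(
                f"well {self.well_id!r}: summaries must be strictly increasing "
                f"in time, got {times}"
            )

    @property
    def times(self) -> list[float]:
        return [s.time_h for s in self.summaries]


def compute_bin_thresholds(
    areas: Sequence[float],
    percentiles: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
    source_scope: str = "",
) -> BinThresholds:
    """Percentile size-bin boundaries over a pool of organoid areas.

    Percentiles are computed with linear interpolation between order
    statistics.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise InsufficientDataError("cannot compute bin thresholds of no areas")
    ranks = tuple(float(p) for p in percentiles)
    if len(ranks) != 4:
        raise ValueError(f"exactly four percentile ranks required, got {ranks}")
    if any(b <= a for a, b in zip(ranks, ranks[1:])) or not all(
        0 < p < 100 for p in ranks
    ):
        raise ValueError(f"percentiles must be strictly increasing in (0, 100): {ranks}")
    q = np.percentile(areas, ranks, method="linear")
    return BinThresholds(*map(float, q), percentiles=ranks, source_scope=source_scope)


def assign_size_bin(record: OrganoidRecord, thresholds: BinThresholds) -> OrganoidRecord:
    """Assign the size category; ties at a boundary fall into the lower bin."""
    area = record.area_px
    idx = int(np.searchsorted(np.asarray(thresholds.values), area, side="left"))
    return replace(record, size_bin=SIZE_BINS[idx])


def summarize_frame(records: Sequence[OrganoidRecord]) -> FrameSummary:
    """Aggregate the organoid records of one time point."""
    records = list(records)
    if not records:
        # Caller supplies time via the surrounding series; a free-standing
        # empty summary carries time 0 and is replaced there.
        return FrameSummary(
            time_h=0.0,
            count=0,
            total_area=0.0,
            mean_area=None,
            mean_eccentricity=None,
            healthy_count=0,
            unhealthy_count=0,
            bin_counts={name: 0 for name in SIZE_BINS},
        )
    times = {r.time_h for r in records}
    if len(times) > 1:
        raise ConsistencyError(f"records mix time points: {sorted(times)}")
    missing = [r.label for r in records if r.health is None or r.size_bin is None]
    if missing:
        raise ConsistencyError(
            f"records {missing} lack a health class or size bin; classify and "
            "bin before summarizing"
        )
    areas = np.array([r.area_px for r in records], dtype=float)
    eccs = np.array([r.eccentricity for r in records], dtype=float)
    bin_counts = {name: 0 for name in SIZE_BINS}
    for r in records:
        bin_counts[r.size_bin] += 1
    healthy = sum(r.health == "healthy" for r in records)
    return FrameSummary(
        time_h=records[0].time_h,
        count=len(records),
        total_area=float(areas.sum()),
        mean_area=float(areas.mean()),
        mean_eccentricity=float(eccs.mean()),
        healthy_count=healthy,
        unhealthy_count=len(records) - healthy,
        bin_counts=bin_counts,
    )


def _metric_value(summary: FrameSummary, metric: str) -> Optional[float]:
    if metric.startswith("bin_"):
        name = metric[len("bin_"):]
        if name not in SIZE_BINS:
            raise KeyError(f"unknown size bin {name!r}")
        return float(summary.bin_counts[name])
    if not hasattr(summary, metric) or metric in ("bin_counts", "time_h"):
        raise KeyError(f"unknown metric {metric!r}")
    value = getattr(summary, metric)
    return None if value is None else float(value)


def normalize_series(series: WellSeries, metric: str) -> list[float]:
    """Ratio of a metric to its value at the first time point.

    The first element is exactly 1.0.  A missing or zero baseline is an
    error naming the well and metric, never an infinity.
    """
    if not series.summaries:
        raise NormalizationError(
            f"well {series.well_id!r}: no summaries to normalize"
        )
    baseline = _metric_value(series.summaries[0], metric)
    if baseline is None or baseline == 0:
        raise NormalizationError(
            f"well {series.well_id!r}, metric {metric!r}: baseline value is "
            f"{baseline!r}; ratios to initial time are undefined"
        )
    out = []
    for summary in series.summaries:
        value = _metric_value(summary, metric)
        out.append(float("nan") if value is None else value / baseline)
    out[0] = 1.0
    return out


def detect_merge_candidates(
    series: WellSeries, area_tolerance: float = 0.1
) -> list[tuple[float, float, int]]:
    """Flag frame transitions bearing the region-level merge signature.

    A transition is flagged when the count decreases while the total area
    does not decrease by more than ``area_tolerance`` (relative to the
    earlier frame): fusing organoids keep their combined area, dying ones do
    not.  Returns ``(t_prev, t_next, count_drop)`` tuples.
    """
    if len(series.summaries) < 2:
        raise ValueError("merge detection needs at least two summaries")
    flags = []
    for prev, nxt in zip(series.summaries, series.summaries[1:]):
        drop = prev.count - nxt.count
        if drop <= 0:
            continue
        if prev.total_area <= 0:
            continue
        if nxt.total_area >= prev.total_area * (1.0 - area_tolerance):
            flags.append((prev.time_h, nxt.time_h, drop))
    return flags


def dose_response_table(
    wells: Sequence[WellSeries],
    metrics: Sequence[str] = NORMALIZED_METRICS + ("unhealthy_fraction",),
) -> pd.DataFrame:
    """Long-format export: one row per (well, time, metric).

    Columns: condition_id, well_id, time_h, metric, value, normalized.  The
    ``unhealthy_fraction`` metric is the unhealthy/total quotient (not
    normalizable; its ``normalized`` column is NaN).  Rows are sorted by
    (condition, well, time, metric-order) for deterministic output.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("dose_response_table needs at least one well")
    seen = set()
    rows = []
    for series in sorted(wells, key=lambda w: (w.condition_id, w.well_id)):
        for summary in series.summaries:
            key = (series.well_id, summary.time_h)
            if key in seen:
                raise ConsistencyError(f"duplicate (well, time) pair {key}")
            seen.add(key)
        normalized = {
            m: series.normalized.get(m) for m in metrics if m != "unhealthy_fraction"
        }
        for i, summary in enumerate(series.summaries):
            for metric in metrics:
                if metric == "unhealthy_fraction":
                    value = (
                        summary.unhealthy_count / summary.count
                        if summary.count
                        else float("nan")
                    )
                    norm = float("nan")
                else:
                    raw = _metric_value(summary, metric)
                    value = float("nan") if raw is None else raw
                    norm_series = normalized.get(metric)
                    norm = (
                        norm_series[i]
                        if norm_series is not None and i < len(norm_series)
                        else float("nan")
                    )
                rows.append(
                    {
                        "condition_id": series.condition_id,
                        "well_id": series.well_id,
                        "time_h": summary.time_h,
                        "metric": metric,
                        "value": value,
                        "normalized": norm,
                    }
                )
    return pd.DataFrame(rows)
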