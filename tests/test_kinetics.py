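"""Size bins, frame aggregates, baseline normalization, merge signature."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoquant.errors import (
    ConsistencyError,
    InsufficientDataError,
    NormalizationError,
)
from organoquant.kinetics import (
    SIZE_BINS,
    BinThresholds,
    FrameSummary,
    WellSeries,
    assign_size_bin,
    compute_bin_thresholds,
    detect_merge_candidates,
    dose_response_table,
    normalize_series,
    summarize_frame,
)
from organoquant.phenotyping import OrganoidRecord

from conftest import brute_force_percentile


def _record(area, time_h=0.0, health="healthy", size_bin="Tiny", label=1,
            ecc=0.2, well="A1", cond="ctrl"):
    return OrganoidRecord(
        well_id=well, condition_id=cond, time_h=time_h, label=label,
        area_px=area, centroid_rc=(0.0, 0.0), mean_intensity=120.0,
        eccentricity=ecc, health=health, size_bin=size_bin,
    )


def _summary(time_h, count, total_area, healthy=None, bins=None):
    healthy = count if healthy is None else healthy
    bin_counts = {name: 0 for name in SIZE_BINS}
    bin_counts["Tiny"] = count
    if bins:
        bin_counts.update(bins)
    return FrameSummary(
        time_h=time_h, count=count, total_area=total_area,
        mean_area=total_area / count if count else None,
        mean_eccentricity=0.2 if count else None,
        healthy_count=healthy, unhealthy_count=count - healthy,
        bin_counts=bin_counts,
    )


def _series(summaries, well="A1", cond="ctrl"):
    return WellSeries(well_id=well, condition_id=cond, summaries=summaries)


class TestBinThresholds:
    def test_distinct_areas_match_interpolation_oracle(self):
        areas = list(range(1, 101))
        th = compute_bin_thresholds(areas)
        expected = tuple(brute_force_percentile(areas, p) for p in (20, 40, 60, 80))
        assert th.values == pytest.approx(expected)
        assert th.values == pytest.approx((20.8, 40.6, 60.4, 80.2))

    def test_constant_areas_collapse_all_thresholds(self):
        th = compute_bin_thresholds([7.0] * 12)
        assert th.values == (7.0, 7.0, 7.0, 7.0)

    def test_thresholds_bounded_by_data(self):
        th = compute_bin_thresholds([10.0, 20.0])
        assert all(10.0 <= q <= 20.0 for q in th.values)

    def test_empty_input_and_bad_ranks_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_bin_thresholds([])
        with pytest.raises(ValueError):
            compute_bin_thresholds([1, 2, 3], percentiles=(80, 60, 40, 20))
        with pytest.raises(ValueError):
            compute_bin_thresholds([1, 2, 3], percentiles=(0, 40, 60, 80))


class TestAssignSizeBin:
    def test_tied_thresholds_half_open_rule(self):
        th = BinThresholds(5, 5, 5, 5)
        assert assign_size_bin(_record(5), th).size_bin == "Tiny"
        assert assign_size_bin(_record(6), th).size_bin == "Huge"

    def test_below_minimum_area_is_tiny(self):
        th = compute_bin_thresholds(list(range(100, 200)))
        assert assign_size_bin(_record(1), th).size_bin == "Tiny"

    def test_uniform_population_fills_bins_evenly(self):
        areas = list(range(1, 101))
        th = compute_bin_thresholds(areas)
        assigned = [assign_size_bin(_record(a), th).size_bin for a in areas]
        # independent oracle: manual interval assignment
        expected_counts = {name: 0 for name in SIZE_BINS}
        bounds = [brute_force_percentile(areas, p) for p in (20, 40, 60, 80)]
        for a in areas:
            idx = sum(a > b for b in bounds)
            expected_counts[SIZE_BINS[idx]] += 1
        for name in SIZE_BINS:
            assert assigned.count(name) == expected_counts[name]
            assert abs(assigned.count(name) - 20) <= 1

    @pytest.mark.parametrize("n", [100, 1000])
    def test_quintile_occupancy_on_random_distinct_areas(self, n):
        rng = np.random.default_rng(n)
        areas = rng.permutation(np.arange(1, 5 * n, 5, dtype=int))[:n]
        th = compute_bin_thresholds(areas)
        counts = {name: 0 for name in SIZE_BINS}
        oracle_counts = {name: 0 for name in SIZE_BINS}
        for a in areas:
            counts[assign_size_bin(_record(int(a)), th).size_bin] += 1
            oracle_counts[SIZE_BINS[sum(a > b for b in th.values)]] += 1
        assert counts == oracle_counts
        for name in SIZE_BINS:
            assert abs(counts[name] - n / 5) <= 1

    def test_threshold_stability_under_new_large_areas(self):
        areas = list(range(1, 101))
        th = compute_bin_thresholds(areas)
        small = [assign_size_bin(_record(a), th).size_bin for a in areas[:60]]
        # adding records above q80 with frozen thresholds changes nothing
        extended = small + [
            assign_size_bin(_record(a), th).size_bin for a in (500, 900)
        ]
        assert extended[:60] == small
        assert set(extended[60:]) == {"Huge"}


class TestSummarizeFrame:
    def test_arithmetic(self):
        records = [
            _record(100, label=1), _record(200, label=2), _record(300, label=3)
        ]
        s = summarize_frame(records)
        assert (s.count, s.total_area, s.mean_area) == (3, 600.0, 200.0)

    def test_empty_input_has_absent_means(self):
        s = summarize_frame([])
        assert s.count == 0 and s.total_area == 0.0
        assert s.mean_area is None and s.mean_eccentricity is None
        assert sum(s.bin_counts.values()) == 0

    def test_health_partition_identity(self):
        records = [
            _record(100, health="healthy", label=1),
            _record(100, health="healthy", label=2),
            _record(100, health="unhealthy", label=3),
        ]
        s = summarize_frame(records)
        assert (s.healthy_count, s.unhealthy_count) == (2, 1)
        assert s.healthy_count + s.unhealthy_count == s.count
        assert sum(s.bin_counts.values()) == s.count

    def test_mixed_times_rejected(self):
        with pytest.raises(ConsistencyError):
            summarize_frame([_record(10, time_h=0.0), _record(10, time_h=4.0)])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=200, max_value=5000),
                st.sampled_from(["healthy", "unhealthy"]),
                st.sampled_from(SIZE_BINS),
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_invariants_hold_for_any_records(self, spec):
        records = [
            _record(area, health=h, size_bin=b, label=i)
            for i, (area, h, b) in enumerate(spec, 1)
        ]
        s = summarize_frame(records)
        assert s.healthy_count + s.unhealthy_count == s.count == len(records)
        assert sum(s.bin_counts.values()) == s.count
        assert s.total_area == sum(r.area_px for r in records)


class TestNormalizeSeries:
    def test_constant_series(self):
        series = _series([_summary(t, 10, 1000.0) for t in (0, 4, 8)])
        assert normalize_series(series, "count") == [1.0, 1.0, 1.0]

    def test_halving_counts(self):
        series = _series(
            [_summary(0, 8, 800.0), _summary(4, 4, 400.0), _summary(8, 2, 200.0)]
        )
        assert normalize_series(series, "count") == [1.0, 0.5, 0.25]

    def test_first_element_exactly_one_for_every_metric(self):
        series = _series(
            [_summary(t, 7, 700.0, healthy=5) for t in (0, 4, 8, 12)]
        )
        for metric in ("count", "total_area", "mean_area", "healthy_count",
                       "bin_Tiny"):
            assert normalize_series(series, metric)[0] == 1.0

    def test_zero_baseline_is_an_error_not_infinity(self):
        series = _series([_summary(0, 0, 0.0), _summary(4, 5, 500.0)])
        with pytest.raises(NormalizationError, match="A1"):
            normalize_series(series, "count")

    def test_unknown_metric_rejected(self):
        series = _series([_summary(0, 1, 100.0)])
        with pytest.raises(KeyError):
            normalize_series(series, "bogus_metric")


class TestDetectMergeCandidates:
    def test_count_drop_with_retained_area_is_flagged(self):
        series = _series([_summary(0, 5, 1000.0), _summary(4, 4, 1010.0)])
        assert detect_merge_candidates(series) == [(0, 4, 1)]

    def test_count_drop_with_area_collapse_is_not_flagged(self):
        series = _series([_summary(0, 5, 1000.0), _summary(4, 4, 500.0)])
        assert detect_merge_candidates(series) == []

    def test_constant_counts_yield_no_flags(self):
        series = _series([_summary(t, 5, 1000.0 + t) for t in (0, 4, 8)])
        assert detect_merge_candidates(series) == []

    def test_needs_two_summaries(self):
        with pytest.raises(ValueError):
            detect_merge_candidates(_series([_summary(0, 5, 1000.0)]))


class TestWellSeries:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ConsistencyError):
            _series([_summary(4, 1, 100.0), _summary(0, 1, 100.0)])


class TestDoseResponseTable:
    def test_cardinality(self):
        series = _series([_summary(0, 5, 1000.0), _summary(4, 6, 1200.0)])
        table = dose_response_table(
            [series], metrics=("count", "total_area", "mean_area", "bin_Tiny")
        )
        assert len(table) == 2 * 4

    def test_roundtrip_to_identical_summaries(self):
        series = _series(
            [_summary(0, 5, 1000.0, healthy=3), _summary(4, 6, 1200.0, healthy=6)]
        )
        table = dose_response_table([series])
        wide = table.pivot_table(
            index="time_h", columns="metric", values="value"
        )
        for s in series.summaries:
            row = wide.loc[s.time_h]
            assert row["count"] == s.count
            assert row["total_area"] == s.total_area
            assert row["healthy_count"] == s.healthy_count
            assert row["bin_Tiny"] == s.bin_counts["Tiny"]

    def test_condition_metadata_shared_between_replicate_wells(self):
        wells = [
            _series([_summary(0, 5, 1000.0)], well="A1", cond="gem_380nM"),
            _series([_summary(0, 4, 900.0)], well="A2", cond="gem_380nM"),
        ]
        table = dose_response_table(wells)
        assert set(table["condition_id"]) == {"gem_380nM"}

    def test_duplicate_well_time_rejected(self):
        dup = [
            _series([_summary(0, 5, 1000.0)], well="A1"),
            _series([_summary(0, 4, 900.0)], well="A1"),
        ]
        with pytest.raises(ConsistencyError):
            dose_response_table(dup)

    def test_deterministic_row_order(self):
        wells = [
            _series([_summary(0, 5, 1000.0)], well="B2", cond="z"),
            _series([_summary(0, 4, 900.0)], well="A1", cond="a"),
        ]
        table = dose_response_table(wells)
        assert table["condition_id"].iloc[0] == "a"
        assert table["condition_id"].iloc[-1] == "z"
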