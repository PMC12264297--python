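"""Hourly regularization, gap exclusion, imputation, summaries, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icpday import preprocess
from icpday.preprocess import (
    aggregate_first_day,
    gap_exclude,
    impute_series,
    normalize_matrix,
    denormalize_matrix,
    round_to_hour,
    summarize,
)

DAY0 = pd.Timestamp("2021-05-01 00:00:00")


def _events(pairs):
    return pd.DataFrame(
        {"subject_id": 1,
         "charttime": [DAY0 + pd.Timedelta(minutes=m) for m, _ in pairs],
         "icp_mmHg": [v for _, v in pairs]}
    )


class TestRoundToHour:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            # nearest-hour rule: 00:29 -> slot 0, 00:41 -> slot 1
            ([(29, 12.0), (41, 14.0)], {0: 12.0, 1: 14.0}),
            # duplicates averaged: 00:50 and 01:10 both round to slot 1
            ([(50, 14.0), (70, 10.0)], {1: 12.0}),
            # half-hour tie rounds up
            ([(30, 8.0)], {1: 8.0}),
            # last half-hour clamps to slot 23
            ([(23 * 60 + 45, 20.0)], {23: 20.0}),
        ],
    )
    def test_slot_assignment(self, pairs, expected):
        values, mask = round_to_hour(_events(pairs), DAY0)
        for slot in range(24):
            if slot in expected:
                assert mask[slot] and values[slot] == pytest.approx(expected[slot])
            else:
                assert not mask[slot]

    def test_on_the_hour_identity(self):
        pairs = [(60 * h, float(h)) for h in range(24)]
        values, mask = round_to_hour(_events(pairs), DAY0)
        assert mask.all()
        assert np.allclose(values, np.arange(24))

    def test_empty_events_fully_missing(self):
        values, mask = round_to_hour(_events([]), DAY0)
        assert not mask.any() and np.isnan(values).all()

    def test_out_of_window_rejected(self):
        with pytest.raises(ValueError):
            round_to_hour(_events([(25 * 60, 1.0)]), DAY0)

    @given(st.lists(st.integers(min_value=0, max_value=24 * 60 - 1), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_every_event_lands_in_exactly_one_slot(self, minutes):
        events = _events([(m, 1.0) for m in minutes])
        _, mask = round_to_hour(events, DAY0)
        slots = np.minimum(np.floor(np.array(minutes) / 60 + 0.5).astype(int), 23)
        assert set(np.flatnonzero(mask)) == set(slots)


class TestGapExclude:
    def test_seven_hour_gap_excluded(self):
        mask = np.ones(24, bool)
        mask[5:12] = False
        assert gap_exclude(mask)

    def test_six_hour_gap_retained(self):
        mask = np.ones(24, bool)
        mask[5:11] = False
        assert not gap_exclude(mask)

    def test_edge_gap_counts(self):
        mask = np.ones(24, bool)
        mask[:7] = False
        assert gap_exclude(mask)

    def test_fully_observed_retained_fully_missing_excluded(self):
        assert not gap_exclude(np.ones(24, bool))
        assert gap_exclude(np.zeros(24, bool))

    def test_matches_brute_force_run_scan(self):
        rng = np.random.default_rng(0)

        def oracle(mask):
            runs, run = [], 0
            for obs in mask:
                run = 0 if obs else run + 1
                runs.append(run)
            return (not mask.any()) or max(runs) > 6

        for _ in range(10_000):
            mask = rng.uniform(size=24) < rng.uniform(0.2, 1.0)
            assert gap_exclude(mask) == oracle(mask)


class TestImpute:
    def test_linear_midpoint(self):
        values = np.full(24, np.nan)
        mask = np.zeros(24, bool)
        values[4], values[6] = 10.0, 14.0
        mask[[4, 6]] = True
        out = impute_series(values, mask)
        assert out[5] == pytest.approx(12.0)

    def test_flat_edges(self):
        values = np.full(24, np.nan)
        mask = np.zeros(24, bool)
        values[2] = 9.0
        mask[2] = True
        values[20] = 15.0
        mask[20] = True
        out = impute_series(values, mask)
        assert np.allclose(out[:2], 9.0) and np.allclose(out[21:], 15.0)

    def test_complete_series_identity(self):
        values = np.linspace(5, 20, 24)
        out = impute_series(values, np.ones(24, bool))
        assert np.array_equal(out, values)

    def test_fully_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_series(np.full(24, np.nan), np.zeros(24, bool))

    @given(st.sets(st.integers(0, 23), min_size=1, max_size=23))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_preserves_observed(self, observed):
        rng = np.random.default_rng(1)
        mask = np.zeros(24, bool)
        mask[sorted(observed)] = True
        values = np.where(mask, rng.uniform(5, 25, 24), np.nan)
        once = impute_series(values, mask)
        assert np.allclose(once[mask], values[mask])
        assert np.allclose(impute_series(once, np.ones(24, bool)), once)


class TestSummarize:
    def test_constant_series(self):
        assert summarize(np.full(24, 10.0)) == (10.0, 0.0)

    def test_alternating_series_sample_variance(self):
        series = np.tile([8.0, 12.0], 12)
        mean, var = summarize(series)
        assert mean == pytest.approx(10.0)
        assert var == pytest.approx(96 / 23)  # denominator n-1 = 23


class TestNormalize:
    def test_two_point_column_zscore(self):
        X = np.array([[9.0], [11.0]])
        Z, _ = normalize_matrix(X)
        assert np.allclose(Z[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.full(5, 7.0), np.arange(5.0)])
        Z, _ = normalize_matrix(X)
        assert np.allclose(Z[:, 0], 0.0)

    def test_columns_standardized(self):
        rng = np.random.default_rng(2)
        X = rng.normal(10, 3, size=(50, 24))
        Z, _ = normalize_matrix(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(3)
        X = rng.normal(12, 4, size=(40, 24))
        for method in ("zscore", "minmax"):
            Z, params = normalize_matrix(X, method=method)
            assert np.allclose(denormalize_matrix(Z, params), X, atol=1e-10)

    def test_minmax_range(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6))
        Z, _ = normalize_matrix(X, method="minmax")
        assert Z.min() >= 0 and Z.max() <= 1

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            normalize_matrix(np.ones((1, 24)))


class TestAggregateFirstDay:
    def test_clinical_aggregations(self):
        long = pd.DataFrame(
            {
                "subject_id": [1] * 7,
                "variable": ["gcs"] * 3 + ["heart_rate"] * 2 + ["fluid_input", "urine_output"],
                "value": [14, 7, 10, 60, 100, 3000, 1800],
            }
        )
        out = aggregate_first_day(
            long,
            {"gcs": "min", "heart_rate": "mean", "fluid_input": "sum", "urine_output": "sum"},
        ).set_index("subject_id")
        assert out.loc[1, "gcs_min"] == 7
        assert out.loc[1, "heart_rate_mean"] == pytest.approx(80.0)
        assert out.loc[1, "fluid_balance_ml"] == pytest.approx(1200.0)

    def test_missing_variable_is_nan_not_error(self):
        long = pd.DataFrame(
            {"subject_id": [1, 2], "variable": ["gcs", "wbc"], "value": [9, 12.0]}
        )
        out = aggregate_first_day(long, {"gcs": "min", "wbc": "max"}).set_index("subject_id")
        assert np.isnan(out.loc[2, "gcs_min"]) and np.isnan(out.loc[1, "wbc_max"])
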