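"""Cohort reading, eligibility, splitting and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tdnode.cohort import (
    Cohort,
    CohortFormatError,
    CohortValidationError,
    DegenerateCohortError,
    EmptyCohortError,
    NormStats,
    PatientRecord,
    UnscalableProfileError,
    filter_eligible,
    fit_norm_stats,
    normalize_profile,
    read_cohort,
    split_train_test,
)


def _write_measurements(tmp_path, rows, name="meas.csv", cols=("subject_id", "time_weeks", "sld_mm")):
    df = pd.DataFrame(rows, columns=list(cols))
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


class TestReadCohort:
    def test_reads_records_sorted_by_time(self, tmp_path):
        rows = [
            ("a", 6.0, 50.0), ("a", -3.0, 55.0), ("a", 12.0, 45.0),
            ("b", 0.0, 70.0), ("b", 18.0, 60.0), ("b", 9.0, 65.0),
        ]
        cohort = read_cohort(_write_measurements(tmp_path, rows))
        assert len(cohort) == 2
        a = cohort["a"]
        assert a.m == 3
        np.testing.assert_array_equal(a.times, [-3.0, 6.0, 12.0])
        np.testing.assert_array_equal(a.sld, [55.0, 50.0, 45.0])

    def test_missing_column_is_format_error(self, tmp_path):
        path = _write_measurements(
            tmp_path, [("a", 1.0)], cols=("subject_id", "time_weeks")
        )
        with pytest.raises(CohortFormatError, match="sld_mm"):
            read_cohort(path)

    def test_duplicate_time_names_subject(self, tmp_path):
        rows = [("a", 6.0, 50.0), ("a", 6.0, 51.0), ("b", 6.0, 40.0)]
        with pytest.raises(CohortValidationError, match="a"):
            read_cohort(_write_measurements(tmp_path, rows))

    def test_non_numeric_sld_rejected(self, tmp_path):
        rows = [("a", 6.0, "big"), ("a", 12.0, 50.0)]
        with pytest.raises(CohortValidationError, match="sld_mm"):
            read_cohort(_write_measurements(tmp_path, rows))

    def test_survival_and_covariates_joined(self, tmp_path):
        meas = _write_measurements(tmp_path, [("a", 0.0, 50.0), ("a", 6.0, 45.0)])
        surv = tmp_path / "surv.csv"
        pd.DataFrame({"subject_id": ["a"], "os_weeks": [80.0], "event": [1]}).to_csv(surv, index=False)
        cov = tmp_path / "cov.csv"
        pd.DataFrame({"subject_id": ["a"], "age": [61.0]}).to_csv(cov, index=False)
        rec = read_cohort(meas, surv, cov)["a"]
        assert rec.os_time == 80.0 and rec.os_event == 1
        assert rec.covariates["age"] == 61.0


class TestEligibility:
    @staticmethod
    def _rec(sid, times):
        times = np.asarray(times, float)
        return PatientRecord(sid, times, 50.0 + np.arange(times.size))

    def test_post_treatment_count_rule(self):
        # post-treatment (time >= 0) counts {0, 1, 2}: only the last is kept
        cohort = Cohort([
            self._rec("none", [-6.0, -1.0]),
            self._rec("one", [-6.0, 4.0]),
            self._rec("two", [-6.0, 0.0, 6.0]),
        ])
        kept = filter_eligible(cohort)
        assert kept.subject_ids == ["two"]

    def test_time_zero_counts_as_post_treatment(self):
        cohort = Cohort([self._rec("z", [-3.0, 0.0, 6.0])])
        assert len(filter_eligible(cohort)) == 1

    def test_single_post_point_excluded_raises_when_empty(self):
        with pytest.raises(EmptyCohortError):
            filter_eligible(Cohort([self._rec("x", [-3.0, 6.0])]))

    def test_idempotent(self, toy_cohort):
        once = filter_eligible(toy_cohort)
        twice = filter_eligible(once)
        assert once.subject_ids == twice.subject_ids


class TestSplit:
    def test_sizes_disjoint_union(self, toy_cohort):
        train, test = split_train_test(toy_cohort, 0.8, seed=4)
        assert (len(train), len(test)) == (8, 2)
        assert set(train.subject_ids).isdisjoint(test.subject_ids)
        assert sorted(train.subject_ids + test.subject_ids) == sorted(toy_cohort.subject_ids)

    def test_deterministic_given_seed(self, toy_cohort):
        a = split_train_test(toy_cohort, 0.8, seed=11)
        b = split_train_test(toy_cohort, 0.8, seed=11)
        assert a[0].subject_ids == b[0].subject_ids

    def test_rounding_at_scale(self):
        records = [
            PatientRecord(f"s{i}", np.array([0.0, 6.0]), np.array([50.0, 40.0]))
            for i in range(1105)
        ]
        train, test = split_train_test(Cohort(records), 0.8, seed=0)
        assert (len(train), len(test)) == (884, 221)


class TestNormStats:
    def test_hand_computed_mean_and_sample_sd(self):
        cohort = Cohort([
            PatientRecord("a", np.array([0.0, 6.0]), np.array([10.0, 20.0])),
            PatientRecord("b", np.array([0.0]), np.array([30.0])),
        ])
        stats = fit_norm_stats(cohort)
        assert stats.mu == pytest.approx(20.0)
        assert stats.sigma == pytest.approx(10.0)  # sample sd, n-1

    def test_identical_values_degenerate(self):
        cohort = Cohort([
            PatientRecord("a", np.array([0.0, 6.0]), np.array([50.0, 50.0])),
        ])
        with pytest.raises(DegenerateCohortError):
            fit_norm_stats(cohort)

    def test_round_trip(self):
        stats = NormStats(mu=20.0, sigma=10.0)
        x = np.array([3.0, 20.0, 91.5])
        np.testing.assert_allclose(stats.denormalize(stats.normalize(x)), x, rtol=1e-9)


class TestNormalizeProfile:
    def test_hand_example_indices_and_scale(self):
        rec = PatientRecord("a", np.array([-3.0, 0.0, 6.0, 12.0, 18.0]), np.full(5, 50.0))
        prof = normalize_profile(rec, NormStats(40.0, 10.0), window=32.0)
        assert (prof.beta, prof.l) == (2, 5)
        assert prof.T == 18.0
        np.testing.assert_allclose(
            prof.tau_tilde, [-1 / 6, 0.0, 1 / 3, 2 / 3, 1.0], atol=1e-4
        )
        assert prof.tau_tilde[prof.l - 1] == 1.0

    def test_truncated_scale_maps_unseen_beyond_one(self):
        rec = PatientRecord("a", np.array([0.0, 6.0, 48.0]), np.full(3, 50.0))
        prof = normalize_profile(rec, NormStats(40.0, 10.0), window=32.0)
        assert (prof.l, prof.T) == (2, 6.0)
        np.testing.assert_allclose(prof.tau_tilde, [0.0, 1.0, 8.0])

    def test_value_at_mean_maps_to_zero(self):
        rec = PatientRecord("a", np.array([0.0, 6.0]), np.array([40.0, 42.0]))
        prof = normalize_profile(rec, NormStats(40.0, 10.0), window=32.0)
        assert prof.y_tilde[0] == 0.0

    def test_no_positive_seen_time_unscalable(self):
        rec = PatientRecord("a", np.array([-6.0, 0.0, 40.0]), np.full(3, 50.0))
        with pytest.raises(UnscalableProfileError):
            normalize_profile(rec, NormStats(40.0, 10.0), window=32.0)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_time_unit_equivariance(self, scale):
        rec = PatientRecord("a", np.array([-4.0, 5.0, 11.0, 40.0]), np.array([60.0, 55.0, 50.0, 52.0]))
        stats = NormStats(50.0, 12.0)
        base = normalize_profile(rec, stats, window=32.0)
        scaled = normalize_profile(rec.with_times(rec.times * scale), stats, window=32.0 * scale)
        np.testing.assert_allclose(scaled.tau_tilde, base.tau_tilde, rtol=1e-12, atol=0)
        assert scaled.tau_tilde[scaled.l - 1] == 1.0
        assert scaled.T == pytest.approx(base.T * scale, rel=1e-12)

    def test_tau_strictly_increasing(self, toy_records):
        stats = NormStats(50.0, 12.0)
        for rec in toy_records:
            prof = normalize_profile(rec, stats, window=32.0)
            assert np.all(np.diff(prof.tau_tilde) > 0)
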