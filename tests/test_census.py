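"""Census metrics: hand-computed examples, brute-force oracles, invariances."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from edload.census import (
    census_at,
    compute_metrics,
    high_acuity_fraction,
    nedocs_inputs,
    occupancy_rate,
    patient_hours,
    time_to_md,
)
from edload.visit_log import Disposition, EDProfile, VisitRecord

from conftest import random_log

T12 = datetime(2017, 9, 1, 12, 0)


def _shift(record: VisitRecord, delta: timedelta) -> VisitRecord:
    def mv(ts):
        return None if ts is None else ts + delta

    return VisitRecord(
        record.visit_id,
        record.site_id,
        record.arrival_ts + delta,
        mv(record.first_md_ts),
        mv(record.departure_ts),
        record.acuity,
        record.disposition,
        mv(record.admit_request_ts),
    )


class TestHandComputedTiny:
    """The 5-visit hand-built log, queried at 12:00 (all values hand-derived)."""

    def test_metric_vector_matches_hand_computation(self, tiny_records, tiny_profile):
        m = compute_metrics(tiny_records, T12, tiny_profile)
        assert m.census == 4  # v5 departs exactly at 12:00 -> excluded
        assert m.occupancy_rate == pytest.approx(4 / 4)
        # overlaps with [11:00, 12:00): v1 1h, v2 1h, v3 0.5h, v4 0.25h, v5 1h
        assert m.patient_hours_raw == pytest.approx(3.75)
        assert m.patient_hours == pytest.approx(3.75 / 4)
        # contributors: v1 0.5h, v2 1.5h, v3 (censored) 0.5h, v4 (censored) 0.25h
        assert m.time_to_md == pytest.approx(2.75 / 4)
        assert m.high_acuity_fraction == pytest.approx(0.5)  # v1 (2), v4 (1) of 4
        assert m.waiting_count == 2  # v3, v4 unseen
        assert m.admit_boarding_count == 1  # v2 requested 11:45
        assert m.longest_admit_wait == pytest.approx(0.25)
        assert m.longest_waiting_room_wait == pytest.approx(0.5)  # v3 arrived 11:30


class TestCensusAt:
    def test_empty_log_counts_zero(self):
        assert census_at([], T12) == 0

    def test_half_open_presence_interval(self):
        rec = VisitRecord("v", "s", datetime(2017, 9, 1, 10), None,
                          datetime(2017, 9, 1, 12), 3, Disposition.DISCHARGED)
        assert census_at([rec], datetime(2017, 9, 1, 11)) == 1
        assert census_at([rec], datetime(2017, 9, 1, 12)) == 0  # departs at query
        assert census_at([rec], datetime(2017, 9, 1, 10)) == 1  # arrival inclusive

    def test_query_outside_observation_window_raises(self):
        rec = VisitRecord("v", "s", datetime(2017, 9, 1, 10), None,
                          datetime(2017, 9, 1, 12), 3, Disposition.DISCHARGED)
        with pytest.raises(ValueError, match="observation window"):
            census_at([rec], datetime(2017, 9, 2, 0))

    def test_matches_boolean_scan_oracle(self):
        rng = np.random.default_rng(1)
        records = random_log(rng, n=200)
        for hour in (6, 12, 20, 30, 40):
            t = datetime(2017, 9, 1) + timedelta(hours=hour)
            expected = sum(
                1
                for r in records
                if r.arrival_ts <= t and (r.departure_ts is None or r.departure_ts > t)
            )
            assert census_at(records, t) == expected


class TestOccupancyRate:
    def test_simple_ratio(self, random_profile):
        rng = np.random.default_rng(2)
        records = random_log(rng, n=120)
        t = datetime(2017, 9, 2, 0)
        assert occupancy_rate(records, t, random_profile) == pytest.approx(
            census_at(records, t) / 20
        )

    def test_identity_census_equals_rate_times_beds(self, random_profile):
        rng = np.random.default_rng(4)
        records = random_log(rng, n=150)
        for hour in range(6, 42, 7):
            t = datetime(2017, 9, 1) + timedelta(hours=hour)
            assert occupancy_rate(records, t, random_profile) * 20 == pytest.approx(
                census_at(records, t), abs=1e-12
            )


class TestPatientHours:
    def test_full_presence_counts_one_hour(self, random_profile):
        rec = VisitRecord("v", "r", datetime(2017, 9, 1, 9), None,
                          datetime(2017, 9, 1, 14), 3, Disposition.DISCHARGED)
        raw, norm = patient_hours([rec], T12, profile=random_profile)
        assert raw == pytest.approx(1.0)
        assert norm == pytest.approx(1.0 / 20)

    def test_empty_window_is_zero(self, random_profile):
        rec = VisitRecord("v", "r", datetime(2017, 9, 1, 13), None,
                          datetime(2017, 9, 1, 14), 3, Disposition.DISCHARGED)
        raw, _ = patient_hours([rec], datetime(2017, 9, 1, 13, 0), profile=random_profile)
        assert raw == 0.0

    def test_matches_per_minute_census_integration(self, random_profile):
        """Trailing-window patient-hours equal the census integral, checked
        against per-minute discretization (exact for minute-resolution logs)."""
        rng = np.random.default_rng(5)
        records = random_log(rng, n=500)
        for hour in (8, 16, 26, 38):
            t = datetime(2017, 9, 1) + timedelta(hours=hour)
            raw, _ = patient_hours(records, t, profile=random_profile)
            ticks = sum(
                census_at(records, t - timedelta(hours=1) + timedelta(minutes=k))
                for k in range(60)
            )
            assert abs(raw - ticks / 60) <= 1 / 120


class TestTimeToMd:
    def test_single_seen_patient(self):
        rec = VisitRecord("v", "s", datetime(2017, 9, 1, 10), datetime(2017, 9, 1, 10, 30),
                          datetime(2017, 9, 1, 14), 3, Disposition.DISCHARGED)
        assert time_to_md([rec], datetime(2017, 9, 1, 11)) == pytest.approx(0.5)

    def test_no_patients_returns_zero(self):
        assert time_to_md([], T12) == 0.0

    def test_mixed_cohort_matches_hand_enumeration(self):
        base = datetime(2017, 9, 1)
        records = [
            # present, seen 40 min after arrival
            VisitRecord("a", "s", base + timedelta(hours=10), base + timedelta(hours=10, minutes=40),
                        base + timedelta(hours=14), 3, Disposition.DISCHARGED),
            # present, unseen: censored elapsed wait 12:00 - 11:15 = 45 min
            VisitRecord("b", "s", base + timedelta(hours=11, minutes=15), None,
                        base + timedelta(hours=13), 3, Disposition.DISCHARGED),
            # departed, but seen inside (11:00, 12:00]: actual wait 30 min
            VisitRecord("c", "s", base + timedelta(hours=11), base + timedelta(hours=11, minutes=30),
                        base + timedelta(hours=11, minutes=50), 3, Disposition.DISCHARGED),
            # departed before the window with contact at 09:10 -> excluded
            VisitRecord("d", "s", base + timedelta(hours=9), base + timedelta(hours=9, minutes=10),
                        base + timedelta(hours=10), 3, Disposition.DISCHARGED),
            # departed, never seen -> excluded (wait undefined)
            VisitRecord("e", "s", base + timedelta(hours=11), None,
                        base + timedelta(hours=11, minutes=45), 3, Disposition.OTHER),
        ]
        expected = (40 / 60 + 45 / 60 + 30 / 60) / 3
        assert time_to_md(records, T12) == pytest.approx(expected)


class TestHighAcuityAndNedocsInputs:
    def test_counting_fraction(self):
        base = datetime(2017, 9, 1, 10)
        records = [
            VisitRecord(f"v{i}", "s", base, None, None, acuity, Disposition.DISCHARGED)
            for i, acuity in enumerate([1, 2, 3, 4])
        ]
        assert high_acuity_fraction(records, T12) == pytest.approx(0.5)

    def test_empty_census_fraction_zero(self):
        assert high_acuity_fraction([], T12) == 0.0

    def test_counting_matches_scan_oracle(self):
        rng = np.random.default_rng(6)
        records = random_log(rng, n=250)
        t = datetime(2017, 9, 2, 4)
        present = [
            r for r in records
            if r.arrival_ts <= t and (r.departure_ts is None or r.departure_ts > t)
        ]
        expected = sum(r.acuity <= 2 for r in present) / len(present)
        assert high_acuity_fraction(records, t) == pytest.approx(expected)

    def test_nedocs_inputs_match_exhaustive_scan(self, random_profile):
        rng = np.random.default_rng(8)
        records = random_log(rng, n=300)
        t = datetime(2017, 9, 2, 2)
        present = [
            r for r in records
            if r.arrival_ts <= t and (r.departure_ts is None or r.departure_ts > t)
        ]
        waiting = [r for r in present if r.first_md_ts is None or r.first_md_ts > t]
        boarding = [r for r in present if r.admit_request_ts is not None and r.admit_request_ts <= t]
        exp_admit = max(((t - r.admit_request_ts).total_seconds() / 3600 for r in boarding), default=0.0)
        exp_wait = max(((t - r.arrival_ts).total_seconds() / 3600 for r in waiting), default=0.0)
        assert nedocs_inputs(records, t, random_profile) == (
            len(waiting), len(boarding), pytest.approx(exp_admit), pytest.approx(exp_wait)
        )

    def test_no_boarders_reports_zero_wait(self):
        rec = VisitRecord("v", "s", datetime(2017, 9, 1, 10), None, None, 3,
                          Disposition.DISCHARGED)
        _, boarders, longest_admit, _ = nedocs_inputs([rec], T12)
        assert boarders == 0 and longest_admit == 0.0

    def test_single_boarder_wait(self):
        rec = VisitRecord("v", "s", datetime(2017, 9, 1, 8), datetime(2017, 9, 1, 8, 30),
                          None, 3, Disposition.ADMITTED,
                          admit_request_ts=datetime(2017, 9, 1, 9))
        _, boarders, longest_admit, _ = nedocs_inputs([rec], T12)
        assert boarders == 1 and longest_admit == pytest.approx(3.0)


class TestInvariances:
    def test_permutation_invariance(self, random_profile):
        rng = np.random.default_rng(9)
        records = random_log(rng, n=150)
        t = datetime(2017, 9, 2, 6)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert compute_metrics(records, t, random_profile) == compute_metrics(
            shuffled, t, random_profile
        )

    def test_time_translation_equivariance(self, random_profile):
        rng = np.random.default_rng(10)
        records = random_log(rng, n=150)
        t = datetime(2017, 9, 2, 6)
        delta = timedelta(days=3, hours=5)
        shifted = [_shift(r, delta) for r in records]
        m0 = compute_metrics(records, t, random_profile)
        m1 = compute_metrics(shifted, t + delta, random_profile)
        assert m0 == type(m0)(**{**vars(m1), "timepoint": m0.timepoint})
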