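"""Shared fixtures: the hand-built tiny log and random-log generators."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from edload.simulate import TINY_PROFILE, TINY_VISITS
from edload.visit_log import Disposition, EDProfile, VisitRecord

BASE = datetime(2017, 9, 1, 0, 0)


@pytest.fixture
def tiny_records():
    return list(TINY_VISITS)


@pytest.fixture
def tiny_profile():
    return TINY_PROFILE


def random_log(
    rng: np.random.Generator,
    n: int = 200,
    span_hours: float = 48.0,
    site_id: str = "r",
) -> list[VisitRecord]:
    """Random minute-resolution visit log with optional missing fields.

    Timestamps land on whole minutes so piecewise-constant census
    integrals are exact on a one-minute grid.
    """
    records = []
    for i in range(n):
        arr_min = int(rng.integers(0, span_hours * 60))
        los_min = int(rng.integers(10, 12 * 60))
        arrival = BASE + timedelta(minutes=arr_min)
        departed = rng.random() < 0.9
        departure = arrival + timedelta(minutes=los_min) if departed else None
        seen = rng.random() < 0.85
        if seen:
            wait = int(rng.integers(0, min(los_min, 180) + 1))
            first_md = arrival + timedelta(minutes=wait)
        else:
            first_md = None
        admitted = rng.random() < 0.3
        if admitted and departed:
            req_min = int(rng.integers(0, los_min + 1))
            admit_req = arrival + timedelta(minutes=req_min)
        else:
            admit_req = None
        records.append(
            VisitRecord(
                visit_id=f"{site_id}{i}",
                site_id=site_id,
                arrival_ts=arrival,
                first_md_ts=first_md,
                departure_ts=departure,
                acuity=int(rng.integers(1, 6)),
                disposition=Disposition.ADMITTED if admitted else Disposition.DISCHARGED,
                admit_request_ts=admit_req,
            )
        )
    return records


@pytest.fixture
def random_profile():
    return EDProfile("r", treatment_beds=20, hospital_beds=400, name="Random")
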