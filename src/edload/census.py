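"""Per-timepoint census metrics computed from a visit log.

All crowding indices are built from the quantities computed here at a
query time ``t``:

* census — patients present, with half-open presence intervals
  ``[arrival, departure)`` so a patient departing exactly at ``t`` is not
  counted at ``t``;
* occupancy rate — census divided by treatment beds (not clamped);
* patient hours — total patient presence-time inside the trailing
  one-hour window, i.e. the integral of the census over ``[t-1h, t)``,
  reported both raw (hours) and normalized by ``treatment_beds × window``
  so it is a dimensionless bed-time utilisation;
* time to MD — mean registration-to-first-physician-contact interval over
  patients present at ``t`` or seen within the trailing window; patients
  present but not yet seen contribute their censored elapsed wait
  (``t - arrival``), so the metric cannot improve as waits lengthen;
* high-acuity fraction — share of present patients at triage level 1-2;
* NEDOCS/sICMED inputs — waiting-room and admission-boarding counts and
  their longest waits.

Patients with an absent departure are treated as present from arrival to
the end of the observation window (right-censoring must not drop census
contribution). All functions accept either a sequence of
:class:`~edload.visit_log.VisitRecord` or a frame prepared once with
:func:`visits_frame`; pass the frame when querying many timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .visit_log import EDProfile, VisitRecord

__all__ = [
    "MetricVector",
    "visits_frame",
    "observation_window",
    "census_at",
    "occupancy_rate",
    "patient_hours",
    "time_to_md",
    "high_acuity_fraction",
    "nedocs_inputs",
    "compute_metrics",
    "metrics_over_grid",
]

HOUR = timedelta(hours=1)
_NS_PER_HOUR = 3.6e12


@dataclass(frozen=True)
class MetricVector:
    """All per-timepoint inputs from which the crowding scores are built."""

    timepoint: datetime
    census: int
    occupancy_rate: float
    patient_hours_raw: float  # hours of patient presence in the trailing window
    patient_hours: float  # raw / (treatment_beds * window); dimensionless
    time_to_md: float  # hours
    high_acuity_fraction: float
    waiting_count: int  # present, no physician contact yet
    admit_boarding_count: int  # present with an admission requested
    longest_admit_wait: float  # hours
    longest_waiting_room_wait: float  # hours


def visits_frame(records: "Sequence[VisitRecord] | pd.DataFrame") -> pd.DataFrame:
    """Columnar view of a visit log (idempotent on an already-built frame)."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "arrival": pd.to_datetime([r.arrival_ts for r in records]),
            "first_md": pd.to_datetime([r.first_md_ts for r in records]),
            "departure": pd.to_datetime([r.departure_ts for r in records]),
            "admit_request": pd.to_datetime([r.admit_request_ts for r in records]),
            "acuity": np.asarray([r.acuity for r in records], dtype=np.int64),
        }
    )


def observation_window(records) -> tuple[pd.Timestamp, pd.Timestamp]:
    """[earliest arrival, latest known timestamp] spanned by the log."""
    df = visits_frame(records)
    if len(df) == 0:
        raise ValueError("empty visit log has no observation window")
    start = df["arrival"].min()
    end = max(
        df["arrival"].max(),
        df["departure"].max(skipna=True),
        df["first_md"].max(skipna=True),
    )
    return start, end


def _check_in_window(df: pd.DataFrame, t: pd.Timestamp) -> None:
    if len(df) == 0:
        return
    start, end = observation_window(df)
    if t < start or t > end:
        raise ValueError(
            f"query time {t} outside observation window [{start}, {end}]"
        )


def _hours(delta_ns: np.ndarray) -> np.ndarray:
    return delta_ns / _NS_PER_HOUR


def _present_mask(df: pd.DataFrame, t: pd.Timestamp) -> np.ndarray:
    arr = df["arrival"].to_numpy()
    dep = df["departure"].to_numpy()
    t64 = np.datetime64(t)
    return (arr <= t64) & (np.isnat(dep) | (dep > t64))


def census_at(records, t: datetime, *, check_window: bool = True) -> int:
    """Number of patients present at ``t`` (half-open interval convention)."""
    df = visits_frame(records)
    if check_window:
        _check_in_window(df, pd.Timestamp(t))
    return int(_present_mask(df, pd.Timestamp(t)).sum())


def occupancy_rate(records, t: datetime, profile: EDProfile) -> float:
    """Census divided by treatment beds; may exceed 1."""
    return census_at(records, t) / profile.treatment_beds


def patient_hours(
    records,
    t: datetime,
    window: timedelta = HOUR,
    profile: EDProfile | None = None,
) -> tuple[float, float]:
    """Summed presence time in the trailing ``window``, raw and normalized.

    Raw value is Σ over records of the overlap of ``[arrival, departure)``
    (open visits extend to the end of the log) with ``[t - window, t)``,
    in hours. Normalized divides by ``treatment_beds × window`` and
    requires ``profile``; without a profile the normalized slot is NaN.
    """
    if window <= timedelta(0):
        raise ValueError("window must be positive")
    df = visits_frame(records)
    t1 = np.datetime64(pd.Timestamp(t))
    t0 = np.datetime64(pd.Timestamp(t) - window)
    arr = df["arrival"].to_numpy()
    dep = df["departure"].to_numpy().copy()
    # open visits: present to end of observation window >= t, so clipping at
    # t1 below makes any value >= t1 equivalent
    dep[np.isnat(dep)] = t1
    lo = np.maximum(arr.astype("datetime64[ns]"), t0)
    hi = np.minimum(dep.astype("datetime64[ns]"), t1)
    overlap = (hi - lo).astype("timedelta64[ns]").astype(np.int64)
    raw = float(_hours(np.clip(overlap, 0, None).sum()))
    if profile is None:
        return raw, float("nan")
    norm = raw / (profile.treatment_beds * (window / HOUR))
    return raw, norm


def time_to_md(records, t: datetime, window: timedelta = HOUR) -> float:
    """Mean wait from registration to first physician contact, in hours.

    Contributing set: patients present at ``t``, plus patients whose first
    physician contact fell inside ``(t - window, t]``. Present patients
    not yet seen contribute the censored elapsed wait ``t - arrival``;
    departed patients with no recorded contact are excluded (their wait is
    undefined, not zero). Returns 0.0 for an empty contributing set.
    """
    df = visits_frame(records)
    t64 = np.datetime64(pd.Timestamp(t))
    w0 = np.datetime64(pd.Timestamp(t) - window)
    arr = df["arrival"].to_numpy()
    md = df["first_md"].to_numpy()
    present = _present_mask(df, pd.Timestamp(t))
    seen_by_t = ~np.isnat(md) & (md <= t64)
    seen_in_window = seen_by_t & (md > w0)
    contributing = present | seen_in_window
    if not contributing.any():
        return 0.0
    elapsed = _hours((t64 - arr).astype(np.int64))
    actual = np.where(seen_by_t, _hours((md - arr).astype(np.int64)), 0.0)
    waits = np.where(seen_by_t, actual, elapsed)
    return float(waits[contributing].mean())


def high_acuity_fraction(records, t: datetime) -> float:
    """Fraction of present patients at the two highest triage levels (0 if none present)."""
    df = visits_frame(records)
    present = _present_mask(df, pd.Timestamp(t))
    n = int(present.sum())
    if n == 0:
        return 0.0
    return float((df["acuity"].to_numpy()[present] <= 2).sum() / n)


def nedocs_inputs(
    records, t: datetime, profile: EDProfile | None = None
) -> tuple[int, int, float, float]:
    """(waiting_count, admit_boarding_count, longest_admit_wait, longest_waiting_room_wait).

    Waiting = present without physician contact by ``t``; boarding =
    present with an admission requested by ``t``. Longest waits are in
    hours, 0.0 when the respective group is empty.
    """
    df = visits_frame(records)
    t64 = np.datetime64(pd.Timestamp(t))
    arr = df["arrival"].to_numpy()
    md = df["first_md"].to_numpy()
    req = df["admit_request"].to_numpy()
    present = _present_mask(df, pd.Timestamp(t))
    waiting = present & (np.isnat(md) | (md > t64))
    boarding = present & ~np.isnat(req) & (req <= t64)
    longest_admit = (
        float(_hours((t64 - req[boarding]).astype(np.int64)).max()) if boarding.any() else 0.0
    )
    longest_wait = (
        float(_hours((t64 - arr[waiting]).astype(np.int64)).max()) if waiting.any() else 0.0
    )
    return int(waiting.sum()), int(boarding.sum()), longest_admit, longest_wait


def compute_metrics(
    records,
    t: datetime,
    profile: EDProfile,
    window: timedelta = HOUR,
) -> MetricVector:
    """All census metrics at one timepoint, as a :class:`MetricVector`."""
    df = visits_frame(records)
    n = census_at(df, t, check_window=False)
    raw, norm = patient_hours(df, t, window, profile)
    waiting, boarding, longest_admit, longest_wait = nedocs_inputs(df, t, profile)
    return MetricVector(
        timepoint=pd.Timestamp(t).to_pydatetime(),
        census=n,
        occupancy_rate=n / profile.treatment_beds,
        patient_hours_raw=raw,
        patient_hours=norm,
        time_to_md=time_to_md(df, t, window),
        high_acuity_fraction=high_acuity_fraction(df, t),
        waiting_count=waiting,
        admit_boarding_count=boarding,
        longest_admit_wait=longest_admit,
        longest_waiting_room_wait=longest_wait,
    )


def metrics_over_grid(
    records,
    timepoints: Sequence[datetime],
    profile: EDProfile,
    window: timedelta = HOUR,
) -> pd.DataFrame:
    """Metric vectors for many timepoints; one row per timepoint."""
    df = visits_frame(records)
    rows = [compute_metrics(df, t, profile, window) for t in timepoints]
    return pd.DataFrame([vars(m) for m in rows])
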