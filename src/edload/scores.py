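"""The four crowding indices: mSEAL, Occupancy Rate, modified NEDOCS, modified sICMED.

The mSEAL (modified Skåne Emergency department Assessment of patient Load)
score maps two EHR-derivable census metrics to a 1-6 workload scale:

    mSEAL = 1.49 + 9.72 · PatientHours + 0.18 · TimeToMD

with PatientHours the bed-normalized trailing-hour patient-hours (see
:mod:`edload.census`), TimeToMD in hours, and the result clamped into
[1, 6]. Crowding is a score strictly above 4.5 (the scale's top quartile).

The comparator indices are external instruments: NEDOCS is a linear
combination of occupancy, boarding and wait terms (here with the
ventilator/trauma-bay term omitted), and sICMED is a count of satisfied
binary crowding criteria (here without the left-without-being-seen and
ambulance-offload items). Their constants live in ``instruments.yaml``
next to this module and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .census import HOUR, MetricVector, compute_metrics, visits_frame
from .visit_log import EDProfile, VisitRecord

__all__ = [
    "MSEAL_INTERCEPT",
    "MSEAL_COEF_PATIENT_HOURS",
    "MSEAL_COEF_TIME_TO_MD",
    "MSEAL_RANGE",
    "MSEAL_CROWDING_THRESHOLD",
    "NEDOCS_ESTABLISHED_THRESHOLD",
    "SICMED_ESTABLISHED_THRESHOLD",
    "ConfigError",
    "ScorePanel",
    "load_instruments",
    "mseal_linear",
    "mseal_score",
    "is_crowded",
    "nedocs_modified",
    "sicmed_modified",
    "score_panel",
    "build_panel",
]

MSEAL_INTERCEPT = 1.49
MSEAL_COEF_PATIENT_HOURS = 9.72
MSEAL_COEF_TIME_TO_MD = 0.18
MSEAL_RANGE = (1.0, 6.0)
#: Crowding is a score strictly over this value (top quartile of the scale).
MSEAL_CROWDING_THRESHOLD = 4.5
#: Published NEDOCS overcrowding threshold (score over 100).
NEDOCS_ESTABLISHED_THRESHOLD = 100.0
#: ICMED-family crowding at 3 or more satisfied criteria.
SICMED_ESTABLISHED_THRESHOLD = 3


class ConfigError(ValueError):
    """An instrument configuration is missing a required entry."""


def load_instruments(path: str | None = None) -> dict[str, Any]:
    """Load instrument constants (NEDOCS coefficients, sICMED items, thresholds)."""
    if path is None:
        text = resources.files(__package__).joinpath("instruments.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def mseal_linear(patient_hours: float, time_to_md: float):
    """Unclamped mSEAL linear form. Inputs must be non-negative.

    ``patient_hours`` is the bed-normalized (dimensionless) trailing-hour
    patient-hours; ``time_to_md`` is in hours. Accepts scalars or arrays.
    """
    ph = np.asarray(patient_hours, dtype=float)
    ttmd = np.asarray(time_to_md, dtype=float)
    if (ph < 0).any() or (ttmd < 0).any():
        raise ValueError("mSEAL inputs must be non-negative")
    out = MSEAL_INTERCEPT + MSEAL_COEF_PATIENT_HOURS * ph + MSEAL_COEF_TIME_TO_MD * ttmd
    return out if out.ndim else float(out)


def mseal_score(patient_hours: float, time_to_md: float):
    """mSEAL score clamped into its published [1, 6] range."""
    out = np.clip(mseal_linear(patient_hours, time_to_md), *MSEAL_RANGE)
    return out if np.ndim(out) else float(out)


def is_crowded(mseal: float) -> bool:
    """Crowded iff the score is strictly over 4.5."""
    return bool(mseal > MSEAL_CROWDING_THRESHOLD)


def nedocs_modified(
    metrics: MetricVector,
    profile: EDProfile,
    constants: Mapping[str, float] | None = None,
) -> float:
    """Modified NEDOCS: the published linear form without the ventilator term.

    Inputs: census/treatment beds, boarders/hospital beds, longest admit
    wait and longest waiting-room wait (hours). Floored at 0.
    """
    c = constants if constants is not None else load_instruments()["nedocs"]
    try:
        score = (
            c["intercept"]
            + c["occupancy"] * (metrics.census / profile.treatment_beds)
            + c["boarder_ratio"] * (metrics.admit_boarding_count / profile.hospital_beds)
            + c["longest_admit_wait"] * metrics.longest_admit_wait
            + c["longest_waiting_room_wait"] * metrics.longest_waiting_room_wait
        )
        floor = c["floor"]
    except KeyError as exc:
        raise ConfigError(f"NEDOCS constants missing entry {exc}") from exc
    return float(max(score, floor))


def sicmed_modified(
    metrics: MetricVector,
    profile: EDProfile,
    config: Mapping[str, Any] | None = None,
) -> int:
    """Modified sICMED: count of satisfied binary crowding criteria.

    Each enabled item compares one metric-vector field (optionally divided
    by treatment beds) against its configured threshold; the score is the
    number of satisfied items, a small non-negative integer.
    """
    cfg = config if config is not None else load_instruments()["sicmed"]
    try:
        items = cfg["items"]
    except (KeyError, TypeError) as exc:
        raise ConfigError("sICMED config has no 'items' section") from exc
    count = 0
    for name, item in items.items():
        try:
            value = float(getattr(metrics, item["metric"]))
            threshold = item["threshold"]
        except (KeyError, AttributeError) as exc:
            raise ConfigError(f"sICMED item '{name}' misconfigured: {exc}") from exc
        if item.get("per_bed", False):
            value /= profile.treatment_beds
        if value >= threshold:
            count += 1
    return count


@dataclass(frozen=True)
class ScorePanel:
    """All four indices plus their inputs at one (site, timepoint)."""

    timepoint: datetime
    site_id: str
    mseal: float
    occupancy_rate: float
    nedocs: float
    sicmed: int
    inputs: MetricVector


def score_panel(
    records: "Sequence[VisitRecord] | pd.DataFrame",
    t: datetime,
    profile: EDProfile,
    window: timedelta = HOUR,
    instruments: Mapping[str, Any] | None = None,
) -> ScorePanel:
    """Compute the metric vector and all four crowding indices at ``t``."""
    inst = instruments if instruments is not None else load_instruments()
    m = compute_metrics(records, t, profile, window)
    return ScorePanel(
        timepoint=m.timepoint,
        site_id=profile.site_id,
        mseal=mseal_score(m.patient_hours, m.time_to_md),
        occupancy_rate=m.occupancy_rate,
        nedocs=nedocs_modified(m, profile, inst["nedocs"]),
        sicmed=sicmed_modified(m, profile, inst["sicmed"]),
        inputs=m,
    )


_PANEL_SCORE_COLUMNS = ("mseal", "occupancy_rate", "nedocs", "sicmed")


def build_panel(
    records: "Sequence[VisitRecord] | pd.DataFrame",
    timepoints: Sequence[datetime],
    profile: EDProfile,
    window: timedelta = HOUR,
    instruments: Mapping[str, Any] | None = None,
) -> pd.DataFrame:
    """Score panel for one site over many timepoints (one row each).

    Columns: site_id, timepoint, the four indices, and every metric-vector
    input — the layout written by
    :func:`edload.visit_log.write_score_panel`.
    """
    inst = instruments if instruments is not None else load_instruments()
    df = visits_frame(records)
    rows = []
    for t in timepoints:
        p = score_panel(df, t, profile, window, inst)
        m = p.inputs
        rows.append(
            {
                "site_id": p.site_id,
                "timepoint": p.timepoint,
                "mseal": p.mseal,
                "occupancy_rate": p.occupancy_rate,
                "nedocs": p.nedocs,
                "sicmed": p.sicmed,
                "census": m.census,
                "patient_hours_raw": m.patient_hours_raw,
                "patient_hours": m.patient_hours,
                "time_to_md": m.time_to_md,
                "high_acuity_fraction": m.high_acuity_fraction,
                "waiting_count": m.waiting_count,
                "admit_boarding_count": m.admit_boarding_count,
                "longest_admit_wait": m.longest_admit_wait,
                "longest_waiting_room_wait": m.longest_waiting_room_wait,
            }
        )
    return pd.DataFrame(rows)
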