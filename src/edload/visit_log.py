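"""Data model and I/O for ED visit logs, site profiles, workload assessments.

The atom of every census computation is the :class:`VisitRecord`: one
patient's timestamped passage through the emergency department (arrival,
first physician contact, departure), plus triage acuity and disposition.
Interchange is plain CSV/YAML with ISO-8601 timestamps at minute
resolution, matching the event-log exports clinical EHR systems produce.

Rows that violate the record invariants are never silently dropped:
readers return the accepted records together with per-row rejection
diagnostics carrying a machine-readable reason code.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Disposition",
    "RaterRole",
    "VisitRecord",
    "EDProfile",
    "TimepointGrid",
    "WorkloadAssessment",
    "RejectedRow",
    "SchemaError",
    "read_visit_log",
    "write_visit_log",
    "read_assessments",
    "write_assessments",
    "read_sites",
    "write_sites",
    "read_grid",
    "write_grid",
    "read_score_panel",
    "write_score_panel",
]


class Disposition(str, enum.Enum):
    ADMITTED = "admitted"
    DISCHARGED = "discharged"
    OTHER = "other"


class RaterRole(str, enum.Enum):
    DOCTOR = "doctor"
    NURSE = "nurse"
    ENROLLED_NURSE = "enrolled_nurse"


class SchemaError(ValueError):
    """A mandatory column is missing or the file layout is unusable."""


@dataclass(frozen=True)
class VisitRecord:
    """One patient visit. Timestamps are timezone-naive local clock times.

    ``departure_ts`` absent means the patient was still in the ED at the
    end of the log; ``first_md_ts`` absent means no physician contact was
    recorded. ``admit_request_ts`` is the time an inpatient admission was
    requested (drives the NEDOCS boarding items) and is only meaningful
    for admitted patients.
    """

    visit_id: str
    site_id: str
    arrival_ts: datetime
    first_md_ts: datetime | None = None
    departure_ts: datetime | None = None
    acuity: int = 3
    disposition: Disposition = Disposition.DISCHARGED
    admit_request_ts: datetime | None = None

    def violations(self) -> list[str]:
        """Reason codes for every invariant this record violates (empty = valid)."""
        codes: list[str] = []
        if self.acuity not in (1, 2, 3, 4, 5):
            codes.append("bad_acuity")
        if self.first_md_ts is not None and self.first_md_ts < self.arrival_ts:
            codes.append("md_before_arrival")
        if self.departure_ts is not None:
            if self.departure_ts < self.arrival_ts:
                codes.append("departure_before_arrival")
            if self.first_md_ts is not None and self.first_md_ts > self.departure_ts:
                codes.append("md_after_departure")
        if self.admit_request_ts is not None:
            if self.admit_request_ts < self.arrival_ts:
                codes.append("admit_request_before_arrival")
            if self.disposition is not Disposition.ADMITTED:
                codes.append("admit_request_without_admission")
        return codes


@dataclass(frozen=True)
class EDProfile:
    """Static site descriptors needed by Occupancy Rate and NEDOCS."""

    site_id: str
    treatment_beds: int
    hospital_beds: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.treatment_beds < 1:
            raise ValueError(f"treatment_beds must be >= 1, got {self.treatment_beds}")
        if self.hospital_beds < 1:
            raise ValueError(f"hospital_beds must be >= 1, got {self.hospital_beds}")


#: The five daily assessment clock times used in the validation study design.
DEFAULT_CLOCK_TIMES = (time(8, 0), time(12, 0), time(16, 0), time(20, 0), time(23, 0))


@dataclass(frozen=True)
class TimepointGrid:
    """Calendar dates crossed with fixed clock times (default 08/12/16/20/23)."""

    dates: tuple[date, ...]
    clock_times: tuple[time, ...] = DEFAULT_CLOCK_TIMES

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.clock_times, self.clock_times[1:])):
            raise ValueError("clock_times must be strictly increasing within a day")

    def timepoints(self) -> list[datetime]:
        return [datetime.combine(d, ct) for d in self.dates for ct in self.clock_times]

    def __len__(self) -> int:
        return len(self.dates) * len(self.clock_times)


@dataclass(frozen=True)
class WorkloadAssessment:
    """One staff member's workload rating, 1 (no workload) to 6 (very high)."""

    site_id: str
    timepoint: datetime
    rater_role: RaterRole
    rating: int

    def violations(self) -> list[str]:
        return [] if self.rating in range(1, 7) else ["rating_out_of_scale"]


@dataclass(frozen=True)
class RejectedRow:
    line_no: int  # 1-based, counting the header as line 1
    reason: str
    detail: str = ""


# ---------------------------------------------------------------------------
# CSV I/O

_VISIT_COLUMNS = (
    "visit_id",
    "site_id",
    "arrival_ts",
    "first_md_ts",
    "departure_ts",
    "acuity",
    "disposition",
    "admit_request_ts",
)
_VISIT_MANDATORY = ("visit_id", "site_id", "arrival_ts", "acuity", "disposition")
_TS_FORMAT = "%Y-%m-%dT%H:%M"


def _parse_ts(text: str) -> datetime:
    return datetime.fromisoformat(text)


def _fmt_ts(ts: datetime | None) -> str:
    return "" if ts is None else ts.strftime(_TS_FORMAT)


def read_visit_log(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[VisitRecord], list[RejectedRow]]:
    """Read a visit-log CSV, validating every row.

    ``schema`` maps canonical field names to the CSV's column names when
    they differ. Returns ``(records, rejects)``; every input line is in
    exactly one of the two.
    """
    colmap = {c: c for c in _VISIT_COLUMNS}
    if schema:
        colmap.update(schema)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canon in _VISIT_MANDATORY:
            if colmap[canon] not in header:
                raise SchemaError(
                    f"{path}: missing mandatory column '{colmap[canon]}' (for field '{canon}')"
                )
        records: list[VisitRecord] = []
        rejects: list[RejectedRow] = []
        for line_no, row in enumerate(reader, start=2):
            try:
                rec = _visit_from_row(row, colmap)
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow(line_no, "unparsable", str(exc)))
                continue
            codes = rec.violations()
            if codes:
                rejects.append(RejectedRow(line_no, codes[0], f"visit_id={rec.visit_id}"))
            else:
                records.append(rec)
    return records, rejects


def _visit_from_row(row: Mapping[str, str], colmap: Mapping[str, str]) -> VisitRecord:
    def get(canon: str) -> str:
        return (row.get(colmap[canon]) or "").strip()

    def opt_ts(canon: str) -> datetime | None:
        text = get(canon)
        return _parse_ts(text) if text else None

    acuity_text = get("acuity")
    try:
        acuity = int(acuity_text)
    except ValueError as exc:
        raise ValueError(f"bad acuity {acuity_text!r}") from exc
    disp_text = get("disposition")
    try:
        disposition = Disposition(disp_text)
    except ValueError as exc:
        raise ValueError(f"bad disposition {disp_text!r}") from exc
    return VisitRecord(
        visit_id=get("visit_id"),
        site_id=get("site_id"),
        arrival_ts=_parse_ts(get("arrival_ts")),
        first_md_ts=opt_ts("first_md_ts"),
        departure_ts=opt_ts("departure_ts"),
        acuity=acuity,
        disposition=disposition,
        admit_request_ts=opt_ts("admit_request_ts"),
    )


def write_visit_log(records: Iterable[VisitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_VISIT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.visit_id,
                    r.site_id,
                    _fmt_ts(r.arrival_ts),
                    _fmt_ts(r.first_md_ts),
                    _fmt_ts(r.departure_ts),
                    r.acuity,
                    r.disposition.value,
                    _fmt_ts(r.admit_request_ts),
                ]
            )


_ASSESSMENT_COLUMNS = ("site_id", "timepoint", "rater_role", "rating")


def read_assessments(path: str | Path) -> tuple[list[WorkloadAssessment], list[RejectedRow]]:
    """Read workload assessments; ratings outside 1-6 are rejected."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _ASSESSMENT_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column '{col}'")
        out: list[WorkloadAssessment] = []
        rejects: list[RejectedRow] = []
        for line_no, row in enumerate(reader, start=2):
            try:
                a = WorkloadAssessment(
                    site_id=row["site_id"].strip(),
                    timepoint=_parse_ts(row["timepoint"].strip()),
                    rater_role=RaterRole(row["rater_role"].strip()),
                    rating=int(row["rating"]),
                )
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow(line_no, "unparsable", str(exc)))
                continue
            codes = a.violations()
            if codes:
                rejects.append(RejectedRow(line_no, codes[0]))
            else:
                out.append(a)
    return out, rejects


def write_assessments(assessments: Iterable[WorkloadAssessment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ASSESSMENT_COLUMNS)
        for a in assessments:
            writer.writerow([a.site_id, _fmt_ts(a.timepoint), a.rater_role.value, a.rating])


# ---------------------------------------------------------------------------
# YAML site profiles and timepoint grids


def read_sites(path: str | Path) -> dict[str, EDProfile]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: expected a mapping of site_id -> profile")
    sites = {}
    for site_id, entry in raw.items():
        sites[str(site_id)] = EDProfile(
            site_id=str(site_id),
            treatment_beds=int(entry["treatment_beds"]),
            hospital_beds=int(entry["hospital_beds"]),
            name=str(entry.get("name", "")),
        )
    return sites


def write_sites(sites: Mapping[str, EDProfile], path: str | Path) -> None:
    payload = {
        sid: {
            "name": p.name,
            "treatment_beds": p.treatment_beds,
            "hospital_beds": p.hospital_beds,
        }
        for sid, p in sites.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_grid(path: str | Path) -> TimepointGrid:
    """Read a timepoint grid: either explicit ``dates`` or a ``start``/``end`` range."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "dates" in raw:
        dates = tuple(date.fromisoformat(str(d)) for d in raw["dates"])
    else:
        start = date.fromisoformat(str(raw["start"]))
        end = date.fromisoformat(str(raw["end"]))
        dates = tuple(
            date.fromordinal(o) for o in range(start.toordinal(), end.toordinal() + 1)
        )
    clock_times = tuple(
        time.fromisoformat(str(ct)) for ct in raw.get("clock_times", [])
    ) or DEFAULT_CLOCK_TIMES
    return TimepointGrid(dates=dates, clock_times=clock_times)


def write_grid(grid: TimepointGrid, path: str | Path) -> None:
    payload = {
        "dates": [d.isoformat() for d in grid.dates],
        "clock_times": [ct.strftime("%H:%M") for ct in grid.clock_times],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Score-panel I/O

_PANEL_FLOAT_DECIMALS = 6


def write_score_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a per-(site, timepoint) score panel to CSV.

    Floats are written at 6 decimals, which round-trips losslessly at
    that precision; an empty panel is an error and no file is written.
    """
    if panel is None or len(panel) == 0:
        raise ValueError("refusing to write an empty score panel")
    df = panel.copy()
    if "timepoint" in df.columns:
        df["timepoint"] = pd.to_datetime(df["timepoint"]).dt.strftime("%Y-%m-%dT%H:%M")
    try:
        df.to_csv(path, index=False, float_format=f"%.{_PANEL_FLOAT_DECIMALS}f")
    except OSError as exc:
        raise OSError(f"failed writing score panel to {path}: {exc}") from exc


def read_score_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "timepoint" in df.columns:
        df["timepoint"] = pd.to_datetime(df["timepoint"])
    return df
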