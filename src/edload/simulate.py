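"""Discrete-event synthetic ED generator with known ground truth.

Emulates the data-generating setting of a multi-site crowding validation
study: timestamped patient visits at several EDs over a study horizon,
plus staff workload assessments (Likert 1-6) at five fixed daily clock
times, correlated with the true load through a known linear link.

Generative model, per site:

* arrivals — nonhomogeneous Poisson process with piecewise-constant
  hourly intensity following a diurnal curve (mid-day peak, overnight
  trough), scaled so a site's expected daily arrivals default to
  ``1.8 × treatment beds``;
* length of stay — lognormal with disposition-specific mean (right-skewed,
  as ED stay distributions are) and common log-scale dispersion;
* first physician contact — arrival plus a delay that grows linearly
  with the occupancy rate at arrival, so waits worsen under load by
  construction;
* admissions — a fixed fraction of visits, with the inpatient-bed request
  placed part-way through the stay (drives the boarding metrics);
* workload — latent workload at an assessment timepoint is
  ``a0 + a1·patient_hours + a2·time_to_md`` computed from the simulated
  log over the trailing hour (the same census machinery used for
  scoring); each rater reports the latent value plus Gaussian noise,
  rounded and clipped to {1..6}. Whole-timepoint missingness can be
  configured, optionally higher under high load (rating sheets not
  collected when staff are too busy).

All randomness flows from a single integer seed through a documented
splitting scheme (seed, site index, stage), so every dataset is exactly
reproducible. Ground truth (link coefficients and per-timepoint latent
workload) is returned alongside each dataset for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import census
from .visit_log import (
    DEFAULT_CLOCK_TIMES,
    Disposition,
    EDProfile,
    RaterRole,
    TimepointGrid,
    VisitRecord,
    WorkloadAssessment,
    write_assessments,
    write_grid,
    write_sites,
    write_visit_log,
)

__all__ = [
    "DEFAULT_SITES",
    "DIURNAL_CURVE",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate_visits",
    "simulate_assessments",
    "simulate_dataset",
    "make_fixture",
]

#: Four site profiles spanning small community to large academic EDs.
DEFAULT_SITES = (
    EDProfile("site_a", treatment_beds=48, hospital_beds=550, name="University A"),
    EDProfile("site_b", treatment_beds=16, hospital_beds=100, name="Community"),
    EDProfile("site_c", treatment_beds=43, hospital_beds=700, name="University B"),
    EDProfile("site_d", treatment_beds=48, hospital_beds=800, name="University C"),
)

#: Hourly arrival-intensity multipliers (normalized to mean 1 in use):
#: mid-day peak, shallow overnight trough — EDs retain substantial census
#: overnight, and the five assessment clock times avoid the deepest trough.
DIURNAL_CURVE = (
    0.45, 0.38, 0.33, 0.30, 0.30, 0.35, 0.50, 0.75,
    1.05, 1.30, 1.45, 1.50, 1.48, 1.45, 1.42, 1.40,
    1.38, 1.35, 1.30, 1.22, 1.10, 0.95, 0.75, 0.55,
)

#: Default expected daily arrivals per site: about 0.75 per treatment bed
#: at the academic sites and 0.5 at the community site, which runs at
#: lower per-bed utilisation. Calibrated so the latent workload spans the
#: 1-6 rating scale without saturating it (see docs/methods.md).
DEFAULT_DAILY_ARRIVALS = {
    "site_a": 36.0,
    "site_b": 8.0,
    "site_c": 32.25,
    "site_d": 36.0,
}

_STAGE_VISITS = 1
_STAGE_ASSESS = 2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults are calibrated so the latent workload spans most of the 1-6
    scale with crowding (mSEAL > 4.5) in roughly the top quartile of
    timepoints, matching the scale's design premise. ``workload_link``
    defaults to the mSEAL coefficients so score and latent workload
    coincide up to rater noise.
    """

    seed: int = 0
    n_days: int = 90
    start_date: date = date(2017, 9, 1)
    sites: tuple[EDProfile, ...] = DEFAULT_SITES
    arrival_rate_curve: tuple[float, ...] = DIURNAL_CURVE
    daily_arrivals: Mapping[str, float] | None = None  # default DEFAULT_DAILY_ARRIVALS
    mean_los: Mapping[str, float] = field(
        default_factory=lambda: {"admitted": 5.0, "discharged": 3.0, "other": 2.0}
    )
    los_shape: float = 0.45  # lognormal sigma (log-scale)
    max_los: float = 12.0  # hours; stays are administratively bounded
    md_delay_base: float = 0.4  # hours, delay at an empty ED
    md_delay_load_slope: float = 6.0  # per unit occupancy rate; ~2.5 h waits when full
    admit_fraction: float = 0.25
    other_fraction: float = 0.05
    admit_request_frac: float = 0.6  # admit request at arrival + frac * LOS
    acuity_distribution: tuple[float, ...] = (0.05, 0.20, 0.40, 0.25, 0.10)
    rater_counts: Mapping[str, int] = field(
        default_factory=lambda: {"doctor": 2, "nurse": 3, "enrolled_nurse": 2}
    )
    rating_noise_sd: float = 0.5  # rating units
    workload_link: tuple[float, float, float] = (1.49, 9.72, 0.18)  # (a0, a1, a2)
    missing_prob: float = 0.0  # whole-timepoint missingness
    missing_prob_high_load: float = 0.0  # extra missingness when latent > 4.5
    clock_times: tuple = DEFAULT_CLOCK_TIMES

    def __post_init__(self) -> None:
        if len(self.arrival_rate_curve) != 24:
            raise ValueError("arrival_rate_curve needs 24 hourly multipliers")
        if abs(sum(self.acuity_distribution) - 1.0) > 1e-9:
            raise ValueError("acuity_distribution must sum to 1")
        if any(v <= 0 for v in self.mean_los.values()):
            raise ValueError("mean LOS must be positive")
        if self.los_shape <= 0 or self.md_delay_base <= 0 or self.max_los <= 0:
            raise ValueError("los_shape, md_delay_base and max_los must be positive")
        if not 0 <= self.admit_fraction <= 1 or not 0 <= self.other_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")

    def site_daily_arrivals(self, profile: EDProfile) -> float:
        if self.daily_arrivals is not None:
            return float(self.daily_arrivals[profile.site_id])
        if profile.site_id in DEFAULT_DAILY_ARRIVALS:
            return DEFAULT_DAILY_ARRIVALS[profile.site_id]
        return 0.75 * profile.treatment_beds

    def grid(self) -> TimepointGrid:
        dates = tuple(
            self.start_date + timedelta(days=i) for i in range(self.n_days)
        )
        return TimepointGrid(dates=dates, clock_times=tuple(self.clock_times))


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    link: tuple[float, float, float]
    latent: pd.DataFrame | None = None  # site_id, timepoint, latent, missing
    config: SimConfig | None = None

    def to_json(self) -> str:
        payload = {
            "link": list(self.link),
            "latent": None
            if self.latent is None
            else {
                "site_id": self.latent["site_id"].tolist(),
                "timepoint": [
                    pd.Timestamp(t).isoformat() for t in self.latent["timepoint"]
                ],
                "latent": self.latent["latent"].round(6).tolist(),
                "missing": self.latent["missing"].astype(int).tolist(),
            },
        }
        return json.dumps(payload, indent=1)


def _rng(seed: int, site_index: int, stage: int) -> np.random.Generator:
    # documented splitting scheme: one root seed, keyed by (site, stage)
    return np.random.default_rng([seed, site_index, stage])


def _floor_minute(ts: np.ndarray) -> np.ndarray:
    return ts.astype("datetime64[m]")


def _simulate_site_visits(
    config: SimConfig, profile: EDProfile, site_index: int
) -> list[VisitRecord]:
    rng = _rng(config.seed, site_index, _STAGE_VISITS)
    n_hours = config.n_days * 24
    curve = np.asarray(config.arrival_rate_curve, dtype=float)
    curve = curve / curve.mean()  # guard: multipliers average to 1
    hourly_rate = config.site_daily_arrivals(profile) / 24.0 * np.tile(
        curve, config.n_days
    )
    counts = rng.poisson(hourly_rate)
    n = int(counts.sum())
    if n == 0:
        return []
    t0 = np.datetime64(datetime.combine(config.start_date, datetime.min.time()))
    hour_index = np.repeat(np.arange(n_hours), counts)
    offsets_h = hour_index + rng.random(n)
    order = np.argsort(offsets_h, kind="stable")
    offsets_h = offsets_h[order]
    arrivals = t0 + (offsets_h * 3600.0).astype("timedelta64[s]")

    disp_draw = rng.random(n)
    dispositions = np.where(
        disp_draw < config.admit_fraction,
        "admitted",
        np.where(disp_draw < config.admit_fraction + config.other_fraction, "other", "discharged"),
    )
    sigma = config.los_shape
    mean_los = np.vectorize(config.mean_los.__getitem__)(dispositions).astype(float)
    mu = np.log(mean_los) - sigma * sigma / 2.0
    los_h = np.minimum(np.exp(rng.normal(mu, sigma)), config.max_los)
    departures = arrivals + (los_h * 3600.0).astype("timedelta64[s]")

    # occupancy at each arrival: earlier arrivals still present
    dep_sorted = np.sort(departures)
    occ = np.arange(n) - np.searchsorted(dep_sorted, arrivals, side="right")
    occ_rate = occ / profile.treatment_beds
    delay_h = config.md_delay_base * (1.0 + config.md_delay_load_slope * occ_rate)
    first_md = arrivals + (delay_h * 3600.0).astype("timedelta64[s]")
    first_md = np.minimum(first_md, departures)

    admit_req = arrivals + (config.admit_request_frac * los_h * 3600.0).astype(
        "timedelta64[s]"
    )
    acuity = rng.choice(
        np.arange(1, 6), size=n, p=np.asarray(config.acuity_distribution)
    )

    arrivals = _floor_minute(arrivals)
    departures = _floor_minute(departures)
    first_md = _floor_minute(first_md)
    admit_req = _floor_minute(admit_req)

    records = []
    for i in range(n):
        admitted = dispositions[i] == "admitted"
        records.append(
            VisitRecord(
                visit_id=f"{profile.site_id}-{i:06d}",
                site_id=profile.site_id,
                arrival_ts=arrivals[i].astype(datetime),
                first_md_ts=first_md[i].astype(datetime),
                departure_ts=departures[i].astype(datetime),
                acuity=int(acuity[i]),
                disposition=Disposition(dispositions[i]),
                admit_request_ts=admit_req[i].astype(datetime) if admitted else None,
            )
        )
    return records


def simulate_visits(config: SimConfig) -> tuple[list[VisitRecord], GroundTruth]:
    """Simulate visit logs for every configured site (reproducible from seed)."""
    records: list[VisitRecord] = []
    for idx, profile in enumerate(config.sites):
        records.extend(_simulate_site_visits(config, profile, idx))
    return records, GroundTruth(link=config.workload_link, config=config)


def simulate_assessments(
    records: Sequence[VisitRecord],
    truth: GroundTruth,
    grid: TimepointGrid,
    config: SimConfig,
) -> list[WorkloadAssessment]:
    """Correlated staff workload ratings at every grid timepoint.

    Latent workload is computed from the simulated log with the same
    trailing-hour census machinery used for scoring; each rater reports
    latent + Gaussian noise, rounded and clipped to {1..6}. Fills
    ``truth.latent`` with the per-timepoint latent values and missingness.
    """
    a0, a1, a2 = config.workload_link
    by_site: dict[str, list[VisitRecord]] = {p.site_id: [] for p in config.sites}
    for r in records:
        by_site.setdefault(r.site_id, []).append(r)
    timepoints = grid.timepoints()
    assessments: list[WorkloadAssessment] = []
    latent_rows = []
    roles = [RaterRole(role) for role in config.rater_counts]
    for idx, profile in enumerate(config.sites):
        rng = _rng(config.seed, idx, _STAGE_ASSESS)
        frame = census.visits_frame(by_site.get(profile.site_id, []))
        for t in timepoints:
            if len(frame):
                _, ph = census.patient_hours(frame, t, profile=profile)
                ttmd = census.time_to_md(frame, t)
            else:
                ph, ttmd = 0.0, 0.0
            latent = a0 + a1 * ph + a2 * ttmd
            p_miss = config.missing_prob + (
                config.missing_prob_high_load if latent > 4.5 else 0.0
            )
            missing = bool(rng.random() < p_miss) if p_miss > 0 else False
            latent_rows.append(
                {
                    "site_id": profile.site_id,
                    "timepoint": t,
                    "latent": latent,
                    "missing": missing,
                }
            )
            for role in roles:
                k = int(config.rater_counts[role.value])
                noise = rng.normal(0.0, config.rating_noise_sd, size=k)
                if missing:
                    continue
                ratings = np.clip(np.rint(latent + noise), 1, 6).astype(int)
                for rating in ratings:
                    assessments.append(
                        WorkloadAssessment(
                            site_id=profile.site_id,
                            timepoint=t,
                            rater_role=role,
                            rating=int(rating),
                        )
                    )
    truth.latent = pd.DataFrame(latent_rows)
    return assessments


@dataclass
class SimResult:
    records: list[VisitRecord]
    assessments: list[WorkloadAssessment]
    truth: GroundTruth
    sites: dict[str, EDProfile]
    grid: TimepointGrid


def simulate_dataset(config: SimConfig) -> SimResult:
    """Visits + assessments + ground truth for the configured study."""
    records, truth = simulate_visits(config)
    grid = config.grid()
    assessments = simulate_assessments(records, truth, grid, config)
    return SimResult(
        records=records,
        assessments=assessments,
        truth=truth,
        sites={p.site_id: p for p in config.sites},
        grid=grid,
    )


#: Hand-written five-visit log used by the ``tiny`` fixture: metrics at
#: 2017-09-01T12:00 are hand-computable (see the test suite).
TINY_VISITS = (
    VisitRecord("v1", "tiny", datetime(2017, 9, 1, 9, 0), datetime(2017, 9, 1, 9, 30),
                datetime(2017, 9, 1, 13, 0), 2, Disposition.DISCHARGED),
    VisitRecord("v2", "tiny", datetime(2017, 9, 1, 10, 0), datetime(2017, 9, 1, 11, 30),
                datetime(2017, 9, 1, 15, 0), 4, Disposition.ADMITTED,
                admit_request_ts=datetime(2017, 9, 1, 11, 45)),
    VisitRecord("v3", "tiny", datetime(2017, 9, 1, 11, 30), None,
                datetime(2017, 9, 1, 12, 30), 3, Disposition.OTHER),
    VisitRecord("v4", "tiny", datetime(2017, 9, 1, 11, 45), None, None, 1,
                Disposition.DISCHARGED),
    VisitRecord("v5", "tiny", datetime(2017, 9, 1, 7, 0), datetime(2017, 9, 1, 7, 20),
                datetime(2017, 9, 1, 12, 0), 5, Disposition.DISCHARGED),
)

TINY_PROFILE = EDProfile("tiny", treatment_beds=4, hospital_beds=100, name="Tiny")

_FIXTURES = {
    "tiny": None,  # handled specially
    "one_day": SimConfig(seed=17, n_days=1, sites=DEFAULT_SITES[:1]),
    "four_sites_3mo": SimConfig(
        seed=17, n_days=90, missing_prob=0.01, missing_prob_high_load=0.04
    ),
}


def make_fixture(name: str, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write a named deterministic dataset (visits/assessments/sites/grid/truth).

    ``tiny`` is a hand-written 5-visit log; ``one_day`` is one site for a
    day; ``four_sites_3mo`` is 4 sites x 90 days x 5 timepoints with a
    little configured missingness. Regeneration with the same seed is
    byte-identical.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "tiny":
        write_visit_log(TINY_VISITS, out / "visits.csv")
        write_sites({TINY_PROFILE.site_id: TINY_PROFILE}, out / "sites.yaml")
        write_grid(
            TimepointGrid(dates=(date(2017, 9, 1),)), out / "grid.yaml"
        )
        return out
    config = _FIXTURES[name]
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    result = simulate_dataset(config)
    write_visit_log(result.records, out / "visits.csv")
    write_assessments(result.assessments, out / "assessments.csv")
    write_sites(result.sites, out / "sites.yaml")
    write_grid(result.grid, out / "grid.yaml")
    (out / "truth.json").write_text(result.truth.to_json())
    return out
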