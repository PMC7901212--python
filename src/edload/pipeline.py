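"""Stage chaining (simulate -> score -> derive -> validate) with a run manifest.

Every output directory gets exactly one ``manifest.json`` recording the
command, config hash, seed, input/output paths, package version and wall
time — enough to audit where any CSV came from. All artifacts are plain
text (CSV/JSON/YAML). A failing stage aborts the run with the stage
named; files already written by the failing stage are renamed with a
``.partial`` suffix rather than deleted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .derivation import stepwise_backward
from .scores import build_panel, load_instruments
from .simulate import SimConfig, make_fixture, simulate_dataset
from .validation import mean_ratings, table3_report
from .visit_log import (
    EDProfile,
    read_assessments,
    read_grid,
    read_sites,
    read_visit_log,
    write_assessments,
    write_grid,
    write_score_panel,
    write_sites,
    write_visit_log,
)

__all__ = ["PipelineError", "run_pipeline", "score_stage", "derive_stage", "validate_stage"]

DEFAULT_CANDIDATES = ("patient_hours", "occupancy_rate", "time_to_md")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(path: str | Path | None) -> str:
    if path is None:
        return "none"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: Path,
    command: str,
    seed: int | None,
    config_path: str | Path | None,
    inputs: list[str],
    outputs: list[str],
) -> None:
    manifest = {
        "command": command,
        "config_hash": _config_hash(config_path),
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "package_version": __version__,
        "timestamp": datetime.now().isoformat(timespec="seconds"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def _sim_config_from_mapping(raw: Mapping[str, Any], seed: int) -> SimConfig:
    kwargs: dict[str, Any] = {"seed": seed}
    simple = {
        "n_days", "los_shape", "md_delay_base", "md_delay_load_slope",
        "admit_fraction", "other_fraction", "admit_request_frac",
        "rating_noise_sd", "missing_prob", "missing_prob_high_load",
    }
    for key, value in raw.items():
        if key in simple:
            kwargs[key] = value
        elif key == "start_date":
            kwargs[key] = date.fromisoformat(str(value))
        elif key == "workload_link":
            kwargs[key] = tuple(float(v) for v in value)
        elif key == "acuity_distribution":
            kwargs[key] = tuple(float(v) for v in value)
        elif key == "arrival_rate_curve":
            kwargs[key] = tuple(float(v) for v in value)
        elif key == "mean_los":
            kwargs[key] = {k: float(v) for k, v in value.items()}
        elif key == "daily_arrivals":
            kwargs[key] = {k: float(v) for k, v in value.items()}
        elif key == "rater_counts":
            kwargs[key] = {k: int(v) for k, v in value.items()}
        elif key == "sites":
            kwargs[key] = tuple(
                EDProfile(
                    site_id=str(sid),
                    treatment_beds=int(s["treatment_beds"]),
                    hospital_beds=int(s["hospital_beds"]),
                    name=str(s.get("name", "")),
                )
                for sid, s in value.items()
            )
        else:
            raise ValueError(f"unknown simulate config key '{key}'")
    return SimConfig(**kwargs)


def simulate_stage(config: Mapping[str, Any], seed: int, out_dir: Path) -> dict[str, Path]:
    sim_config = _sim_config_from_mapping(config or {}, seed)
    result = simulate_dataset(sim_config)
    paths = {
        "visits": out_dir / "visits.csv",
        "assessments": out_dir / "assessments.csv",
        "sites": out_dir / "sites.yaml",
        "grid": out_dir / "grid.yaml",
        "truth": out_dir / "truth.json",
    }
    write_visit_log(result.records, paths["visits"])
    write_assessments(result.assessments, paths["assessments"])
    write_sites(result.sites, paths["sites"])
    write_grid(result.grid, paths["grid"])
    paths["truth"].write_text(result.truth.to_json())
    return paths


def score_stage(
    visits_path: str | Path,
    sites_path: str | Path,
    grid_path: str | Path,
    out_path: str | Path,
    window_hours: float = 1.0,
    instruments_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a visit log and score every (site, grid timepoint); write panel CSV."""
    records, _rejects = read_visit_log(visits_path)
    sites = read_sites(sites_path)
    grid = read_grid(grid_path)
    instruments = load_instruments(instruments_path)
    window = timedelta(hours=window_hours)
    frames = []
    for site_id, profile in sites.items():
        site_records = [r for r in records if r.site_id == site_id]
        frames.append(
            build_panel(site_records, grid.timepoints(), profile, window, instruments)
        )
    panel = pd.concat(frames, ignore_index=True)
    write_score_panel(panel, out_path)
    return panel


def derive_stage(
    panel_path: str | Path,
    assessments_path: str | Path,
    out_path: str | Path,
    alpha: float = 0.05,
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    per_site: bool = False,
) -> dict[str, Any]:
    """Stepwise-OLS derivation of a workload model from the score panel.

    The outcome is the mean rating across all raters at each matched
    (site, timepoint); derivation pools sites by default.
    """
    from .visit_log import read_score_panel

    panel = read_score_panel(panel_path)
    assessments, _ = read_assessments(assessments_path)
    ratings = mean_ratings(assessments)
    merged = panel.merge(ratings, on=["site_id", "timepoint"], how="inner")

    def one_fit(df: pd.DataFrame) -> dict[str, Any]:
        fit = stepwise_backward(df[list(candidates)], df["mean_rating"], alpha=alpha)
        return {
            "retained_terms": list(fit.retained_terms),
            "coefficients": fit.coefficients,
            "p_values": fit.p_values,
            "std_errors": fit.std_errors,
            "r_squared": fit.r_squared,
            "n": fit.n,
            "intercept_only": fit.intercept_only,
            "eliminated": list(fit.eliminated),
        }

    if per_site:
        payload: dict[str, Any] = {
            "per_site": {
                str(site): one_fit(grp) for site, grp in merged.groupby("site_id")
            },
            "alpha": alpha,
            "candidates": list(candidates),
        }
    else:
        payload = {"pooled": one_fit(merged), "alpha": alpha, "candidates": list(candidates)}
    Path(out_path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return payload


def validate_stage(
    panel_path: str | Path,
    assessments_path: str | Path,
    out_path: str | Path,
    threshold: float = 4.5,
    bootstrap: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """ROC validation of every score against dichotomized workload; writes the report CSV."""
    from .visit_log import read_score_panel

    panel = read_score_panel(panel_path)
    assessments, _ = read_assessments(assessments_path)
    report, counts = table3_report(
        panel, assessments, threshold=threshold, B=bootstrap, seed=seed
    )
    report.to_csv(out_path, index=False, float_format="%.6f")
    counts_path = Path(out_path).with_suffix(".counts.json")
    counts_path.write_text(json.dumps(counts, indent=1) + "\n")
    return report


def run_pipeline(config_path: str | Path, seed: int, out_dir: str | Path) -> Path:
    """Chain simulate -> score -> derive -> validate from one YAML config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    outputs: list[str] = []
    stage = "simulate"
    stage_outputs: list[Path] = []
    try:
        sim_paths = simulate_stage(config.get("simulate", {}), seed, out)
        stage_outputs = list(sim_paths.values())
        outputs += [str(p) for p in stage_outputs]

        stage = "score"
        panel_path = out / "panel.csv"
        stage_outputs = [panel_path]
        score_cfg = config.get("score", {}) or {}
        score_stage(
            sim_paths["visits"],
            sim_paths["sites"],
            sim_paths["grid"],
            panel_path,
            window_hours=float(score_cfg.get("window_hours", 1.0)),
        )
        outputs.append(str(panel_path))

        stage = "derive"
        fit_path = out / "fit.json"
        stage_outputs = [fit_path]
        derive_cfg = config.get("derive", {}) or {}
        derive_stage(
            panel_path,
            sim_paths["assessments"],
            fit_path,
            alpha=float(derive_cfg.get("alpha", 0.05)),
            candidates=tuple(derive_cfg.get("candidates", DEFAULT_CANDIDATES)),
            per_site=bool(derive_cfg.get("per_site", False)),
        )
        outputs.append(str(fit_path))

        stage = "validate"
        table_path = out / "table3.csv"
        stage_outputs = [table_path]
        validate_cfg = config.get("validate", {}) or {}
        validate_stage(
            panel_path,
            sim_paths["assessments"],
            table_path,
            threshold=float(validate_cfg.get("threshold", 4.5)),
            bootstrap=int(validate_cfg.get("bootstrap", 2000)),
            seed=seed,
        )
        outputs += [str(table_path), str(table_path.with_suffix(".counts.json"))]
    except Exception as exc:
        for p in stage_outputs:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise PipelineError(stage, exc) from exc
    write_manifest(out, "run", seed, config_path, [str(config_path)], outputs)
    return out
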