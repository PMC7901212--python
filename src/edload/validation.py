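"""Validation statistics: workload dichotomization, ROC, Youden cutoff, bootstrap CI.

The validation outcome is crowding at a timepoint, defined as a mean
staff workload rating of 4.5 or higher (inclusive) on the 1-6 Likert
scale. Each crowding score is evaluated against that binary outcome with
a receiver operating characteristic curve; discrimination is summarised
by the area under the curve (AuROC) with a stratified percentile
bootstrap confidence interval, and an operating cutoff is chosen by the
Youden index J = sensitivity + specificity - 1 (ties broken toward
higher specificity).

Note the deliberate asymmetry with the score side: crowding by workload
is inclusive at 4.5 ("4.5 or higher") while crowding by mSEAL is strict
("over 4.5"); both conventions follow the instrument definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .visit_log import WorkloadAssessment

__all__ = [
    "WORKLOAD_CROWDING_THRESHOLD",
    "RocResult",
    "UndefinedRocError",
    "mean_ratings",
    "dichotomize",
    "roc_curve",
    "auc",
    "auroc_ci",
    "youden_cutoff",
    "evaluate_score",
    "table3_report",
]

#: Mean workload rating at or above which a timepoint counts as crowded.
WORKLOAD_CROWDING_THRESHOLD = 4.5


class UndefinedRocError(ValueError):
    """ROC is undefined when only one outcome class is present."""


@dataclass(frozen=True)
class RocResult:
    """Discrimination summary for one score against the crowding outcome."""

    score_name: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def _assessments_frame(assessments) -> pd.DataFrame:
    if isinstance(assessments, pd.DataFrame):
        return assessments
    return pd.DataFrame(
        {
            "site_id": [a.site_id for a in assessments],
            "timepoint": pd.to_datetime([a.timepoint for a in assessments]),
            "rating": [a.rating for a in assessments],
        }
    )


def mean_ratings(assessments) -> pd.DataFrame:
    """Mean rating per (site_id, timepoint): columns site_id, timepoint, mean_rating, n_raters."""
    df = _assessments_frame(assessments)
    out = (
        df.groupby(["site_id", "timepoint"], as_index=False)
        .agg(mean_rating=("rating", "mean"), n_raters=("rating", "size"))
    )
    return out


def dichotomize(
    assessments,
    threshold: float = WORKLOAD_CROWDING_THRESHOLD,
) -> pd.DataFrame:
    """Binary crowding outcome per timepoint: 1 iff mean rating >= threshold.

    Timepoints with at least one rating are retained; the returned frame
    has columns site_id, timepoint, mean_rating, n_raters, crowded.
    """
    out = mean_ratings(assessments)
    out["crowded"] = (out["mean_rating"] >= threshold).astype(int)
    return out


def roc_curve(scores, outcomes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) with a threshold at every distinct score value.

    The curve runs from (0, 0) to (1, 1); ``thresholds[0]`` is +inf
    (nothing classified positive). Raises if only one class is present.
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedRocError("both outcome classes required for a ROC curve")
    fpr, tpr, thr = skmetrics.roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, thr


def auc(scores, outcomes) -> float:
    """Area under the ROC curve (trapezoidal; equals the tie-corrected U-statistic)."""
    fpr, tpr, _ = roc_curve(scores, outcomes)
    return float(skmetrics.auc(fpr, tpr))


def _auc_from_ranked(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC of (B, n_pos) vs (B, n_neg) score blocks via midranks."""
    both = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(both, axis=1)  # midranks handle ties
    n_pos, n_neg = pos.shape[1], neg.shape[1]
    rank_sum = ranks[:, :n_pos].sum(axis=1)
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auroc_ci(
    scores,
    outcomes,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Point AUC with a stratified percentile-bootstrap confidence interval.

    Positives and negatives are resampled separately (stratification keeps
    both classes in every replicate). Reproducible given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedRocError("both outcome classes required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_idx = rng.integers(0, len(pos), size=(B, len(pos)))
    neg_idx = rng.integers(0, len(neg), size=(B, len(neg)))
    boots = _auc_from_ranked(pos[pos_idx], neg[neg_idx])
    lo, hi = np.quantile(boots, [(1 - level) / 2, (1 + level) / 2])
    point = auc(s, y)
    # the interval always brackets the point estimate
    return point, float(min(lo, point)), float(max(hi, point))


def youden_cutoff(
    fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray
) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing J = sens + spec - 1.

    Candidate cutoffs are the finite thresholds (distinct score values);
    ties on J are broken toward higher specificity (lower fpr), then
    toward the higher cutoff.
    """
    finite = np.isfinite(thresholds)
    fpr, tpr, thresholds = fpr[finite], tpr[finite], thresholds[finite]
    j = tpr - fpr
    best = j.max()
    candidates = np.flatnonzero(j == best)
    # lower fpr wins, then higher threshold
    order = sorted(candidates, key=lambda i: (fpr[i], -thresholds[i]))
    i = order[0]
    return float(thresholds[i]), float(tpr[i]), float(1.0 - fpr[i])


def evaluate_score(
    name: str,
    scores,
    outcomes,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
) -> RocResult:
    """Full discrimination summary (AUC, CI, Youden cutoff, sens/spec) for one score."""
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    point, lo, hi = auroc_ci(s, y, B=B, seed=seed)
    fpr, tpr, thr = roc_curve(s, y)
    cutoff, sens, spec = youden_cutoff(fpr, tpr, thr)
    return RocResult(
        score_name=name,
        auc=point,
        ci_low=lo,
        ci_high=hi,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
    )


def table3_report(
    panel: pd.DataFrame,
    assessments,
    threshold: float = WORKLOAD_CROWDING_THRESHOLD,
    score_columns: Sequence[str] = ("mseal", "occupancy_rate", "nedocs", "sicmed"),
    B: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per score: AUC (95% CI), Youden cutoff, sensitivity, specificity.

    Panels and assessments are matched listwise on (site_id, timepoint);
    unmatched timepoints on either side are dropped and counted in the
    returned ``counts`` dict (n_panel, n_assessed, n_matched).
    """
    outcome = dichotomize(assessments, threshold)
    merged = panel.merge(outcome, on=["site_id", "timepoint"], how="inner")
    counts = {
        "n_panel": int(len(panel)),
        "n_assessed": int(len(outcome)),
        "n_matched": int(len(merged)),
    }
    if len(merged) == 0:
        raise ValueError("no matched (site, timepoint) pairs between panel and assessments")
    rows = []
    y = merged["crowded"].to_numpy()
    for i, name in enumerate(score_columns):
        # deterministic child seed per score, so rows are independently reproducible
        child = np.random.default_rng([int(seed), i])
        res = evaluate_score(name, merged[name].to_numpy(dtype=float), y, B=B, seed=child)
        rows.append(
            {
                "model": name,
                "auroc": res.auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "cutoff": res.cutoff,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
            }
        )
    return pd.DataFrame(rows), counts
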