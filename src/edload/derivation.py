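"""Score derivation: OLS with stepwise backward elimination against workload.

The derivation regresses the mean staff workload rating at each timepoint
on candidate census metrics, then iteratively removes the single least
significant term (largest two-sided t-test p-value) while any term has
p >= alpha, refitting after each removal. The default alpha of 0.05
matches the conventional two-tailed significance level. Ties on p-value
are broken by removing the term with the smaller absolute standardized
coefficient, then lexicographically, so the procedure is deterministic
and invariant to predictor column order.

Correlations are summarised as the coefficient of determination r²; for
a single-predictor fit this equals the squared Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionFit", "SingularDesignError", "fit_ols", "stepwise_backward", "r_squared_by_site"]


class SingularDesignError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class RegressionFit:
    """Result of an OLS fit (possibly after stepwise elimination)."""

    retained_terms: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    p_values: dict[str, float]
    std_errors: dict[str, float]
    r_squared: float
    n: int
    intercept_only: bool = False
    eliminated: tuple[str, ...] = field(default=())


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name columns whose removal restores full rank
        suspects = []
        for col in X.columns:
            if col == "const":
                continue
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                suspects.append(col)
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {suspects or list(X.columns)}"
        )


def fit_ols(design: pd.DataFrame, outcome) -> RegressionFit:
    """Ordinary least squares of ``outcome`` on the columns of ``design``.

    Requires more observations than parameters and no missing cells.
    """
    y = np.asarray(outcome, dtype=float)
    if design.isna().any().any() or np.isnan(y).any():
        raise ValueError("design/outcome contain missing values")
    n, k = design.shape
    if n <= k + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={k})")
    X = sm.add_constant(design.astype(float), has_constant="add")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    params = res.params
    pvals = res.pvalues
    bse = res.bse

    def key(name: str) -> str:
        return "intercept" if name == "const" else name

    return RegressionFit(
        retained_terms=tuple(c for c in design.columns),
        coefficients={key(c): float(params[c]) for c in X.columns},
        p_values={key(c): float(pvals[c]) for c in X.columns},
        std_errors={key(c): float(bse[c]) for c in X.columns},
        r_squared=float(res.rsquared),
        n=int(n),
    )


def stepwise_backward(
    design: pd.DataFrame,
    outcome,
    alpha: float = 0.05,
) -> RegressionFit:
    """Backward elimination: drop the worst term while any p >= alpha.

    One term is removed per iteration and the model refit. If every term
    is eliminated the intercept-only fit is returned with
    ``intercept_only=True``.
    """
    y = np.asarray(outcome, dtype=float)
    current = design.copy()
    eliminated: list[str] = []
    while current.shape[1] > 0:
        fit = fit_ols(current, y)
        term_p = {t: fit.p_values[t] for t in fit.retained_terms}
        worst_p = max(term_p.values())
        if worst_p < alpha:
            return RegressionFit(
                retained_terms=fit.retained_terms,
                coefficients=fit.coefficients,
                p_values=fit.p_values,
                std_errors=fit.std_errors,
                r_squared=fit.r_squared,
                n=fit.n,
                eliminated=tuple(eliminated),
            )
        ties = [t for t, p in term_p.items() if p == worst_p]
        if len(ties) > 1:
            # smaller |standardized coefficient| goes first, then lexicographic
            std = current.std(ddof=1)
            ties.sort(key=lambda t: (abs(fit.coefficients[t]) * float(std[t]), t))
        current = current.drop(columns=[ties[0]])
        eliminated.append(ties[0])
    # intercept-only
    mean = float(np.mean(y))
    return RegressionFit(
        retained_terms=(),
        coefficients={"intercept": mean},
        p_values={"intercept": float("nan")},
        std_errors={"intercept": float(np.std(y, ddof=1) / np.sqrt(len(y)))},
        r_squared=0.0,
        n=len(y),
        intercept_only=True,
        eliminated=tuple(eliminated),
    )


def r_squared_by_site(
    panel: pd.DataFrame,
    mean_ratings: pd.DataFrame,
    score_columns: tuple[str, ...] = ("mseal", "occupancy_rate", "nedocs", "sicmed"),
    min_timepoints: int = 3,
) -> pd.DataFrame:
    """Per-site, per-score r² of mean workload rating on the score.

    ``panel`` has one row per (site_id, timepoint) with score columns;
    ``mean_ratings`` has columns site_id, timepoint, mean_rating.
    Sites with fewer than ``min_timepoints`` matched timepoints are
    excluded with a warning; a score constant over the matched timepoints
    yields NaN (the correlation is undefined).
    """
    merged = panel.merge(mean_ratings, on=["site_id", "timepoint"], how="inner")
    rows = []
    for site, grp in merged.groupby("site_id"):
        if len(grp) < min_timepoints:
            warnings.warn(
                f"site {site}: only {len(grp)} matched timepoints (<{min_timepoints}); excluded"
            )
            continue
        row: dict[str, object] = {"site_id": site, "n_timepoints": len(grp)}
        y = grp["mean_rating"].to_numpy(dtype=float)
        for score in score_columns:
            x = grp[score].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                row[score] = float("nan")
            else:
                r = np.corrcoef(x, y)[0, 1]
                row[score] = float(r * r)
        rows.append(row)
    return pd.DataFrame(rows)
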