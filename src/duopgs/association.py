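"""Per-decile logistic association and inverse-variance meta-analysis.

The exposure of interest is the within-cohort decile (1..10) of a genetic
score, entered as a continuous covariate, so the reported odds ratio is "per
1 decile higher GS".  Cohort-level estimates for the same (score, outcome)
pair are pooled by fixed-effect inverse-variance weighting with Cochran's Q
for between-study heterogeneity:

    beta_pooled = sum(b_k / se_k^2) / sum(1 / se_k^2)
    se_pooled   = (sum 1/se_k^2)^(-1/2)
    Q           = sum (b_k - beta_pooled)^2 / se_k^2  ~  chi^2(k - 1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenotype import OutcomeLabels, case_control
from .scores import ScoreSet

__all__ = [
    "AssocResult",
    "MetaResult",
    "fit_logistic",
    "fit_joint",
    "fit_secondary",
    "meta_fixed",
    "results_to_frame",
]

HETEROGENEITY_ALPHA = 0.05


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE does not exist."""


@dataclass
class AssocResult:
    """Log-odds per decile of one score for one outcome in one cohort."""

    score_role: str
    outcome: str
    cohort_id: str
    beta: float
    se: float
    n_cases: int
    n_controls: int
    adjusted_for: list[str] = field(default_factory=list)
    quasi_separation: bool = False

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + 1.96 * self.se))

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta) / self.se))


@dataclass
class MetaResult:
    """Fixed-effect pooled estimate with Cochran's Q heterogeneity test."""

    score_role: str
    outcome: str
    pooled_beta: float
    pooled_se: float
    q_stat: float
    q_df: int
    n_studies: int

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.pooled_beta - 1.96 * self.pooled_se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.pooled_beta + 1.96 * self.pooled_se))

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.pooled_beta) / self.pooled_se))

    @property
    def q_p(self) -> float:
        return float(stats.chi2.sf(self.q_stat, self.q_df)) if self.q_df > 0 else 1.0

    @property
    def heterogeneous(self) -> bool:
        return self.q_p < HETEROGENEITY_ALPHA


def _exposure_values(scores: ScoreSet, use_deciles: bool) -> np.ndarray:
    if use_deciles:
        if scores.decile is None:
            raise ValueError("scores have no decile assignment; run to_deciles first")
        return scores.decile.astype(float)
    return scores.score


def _build_covariates(
    phenotypes: pd.DataFrame | None,
    covariates: list[str],
    n: int,
) -> tuple[np.ndarray, list[str]]:
    """Covariate design columns; constant covariates dropped with a warning."""
    cols, names = [], []
    for cov in covariates:
        if cov == "sex":
            x = (phenotypes["sex"].to_numpy(dtype=object) == "male").astype(float)
        elif cov == "gestational_age":
            x = phenotypes["gestational_age_wk"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        if np.all(x == x[0]):
            warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=3)
            continue
        cols.append(x)
        names.append(cov)
    if not cols:
        return np.empty((n, 0)), []
    return np.column_stack(cols), names


def _fit(
    y: np.ndarray, X: np.ndarray, exposure_names: list[str]
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic MLE via statsmodels; returns (coef, se, quasi_separation)."""
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (collinear exposures: {exposure_names})"
        )
    quasi = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and friends
            raise SeparationError(
                f"logistic fit failed for exposures {exposure_names}: {exc}"
            ) from exc
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(
                w.message
            ).lower():
                quasi = True
    fitted = res.predict(X)
    if np.any(fitted < 1e-10) | np.any(fitted > 1 - 1e-10):
        quasi = True
    se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(se)):
        raise SeparationError(
            f"infinite standard errors (separation) for exposures {exposure_names}"
        )
    return np.asarray(res.params, dtype=float), se, quasi


def _linear_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = sm.OLS(y, X).fit()
    return np.asarray(res.params, dtype=float), np.asarray(res.bse, dtype=float)


def fit_logistic(
    labels: OutcomeLabels,
    exposure: ScoreSet,
    outcome: str,
    phenotypes: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    cohort_id: str = "",
    use_deciles: bool = True,
    linear_probability: bool = False,
) -> AssocResult:
    """Single-exposure case-control fit: log-odds of ``outcome`` per decile.

    ``labels`` and ``exposure`` must cover the same individuals in the same
    order.  Optional covariates ("sex", "gestational_age") are looked up in
    ``phenotypes``.  ``linear_probability=True`` swaps the logistic link for
    OLS on the 0/1 outcome (sensitivity analysis only).
    """
    y, include = case_control(labels, outcome)
    x = _exposure_values(exposure, use_deciles)
    if np.all(x == x[0]):
        raise ValueError("exposure is constant")
    covariates = covariates or []
    C, cov_names = _build_covariates(phenotypes, covariates, len(y))
    X = np.column_stack([np.ones(len(y)), x, C])[include]
    yy = y[include]
    if linear_probability:
        coef, se = _linear_fit(yy, X)
        quasi = False
    else:
        coef, se, quasi = _fit(yy, X, [exposure.score_role])
    return AssocResult(
        score_role=exposure.score_role,
        outcome=outcome,
        cohort_id=cohort_id,
        beta=float(coef[1]),
        se=float(se[1]),
        n_cases=int(yy.sum()),
        n_controls=int(len(yy) - yy.sum()),
        adjusted_for=cov_names,
        quasi_separation=quasi,
    )


def fit_joint(
    labels: OutcomeLabels,
    fetal_scores: ScoreSet,
    maternal_scores: ScoreSet,
    outcome: str,
    phenotypes: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    cohort_id: str = "",
    use_deciles: bool = True,
    linear_probability: bool = False,
) -> tuple[AssocResult, AssocResult]:
    """Both duo scores in one model, each adjusted for the other."""
    y, include = case_control(labels, outcome)
    x_f = _exposure_values(fetal_scores, use_deciles)
    x_m = _exposure_values(maternal_scores, use_deciles)
    covariates = covariates or []
    C, cov_names = _build_covariates(phenotypes, covariates, len(y))
    X = np.column_stack([np.ones(len(y)), x_f, x_m, C])[include]
    yy = y[include]
    names = [fetal_scores.score_role, maternal_scores.score_role]
    if linear_probability:
        coef, se = _linear_fit(yy, X)
        quasi = False
    else:
        coef, se, quasi = _fit(yy, X, names)
    n_cases = int(yy.sum())
    n_controls = int(len(yy) - n_cases)
    results = []
    for k, (role, other) in enumerate(zip(names, names[::-1]), start=1):
        results.append(
            AssocResult(
                score_role=role,
                outcome=outcome,
                cohort_id=cohort_id,
                beta=float(coef[k]),
                se=float(se[k]),
                n_cases=n_cases,
                n_controls=n_controls,
                adjusted_for=[f"{other}_gs"] + cov_names,
                quasi_separation=quasi,
            )
        )
    return results[0], results[1]


def fit_secondary(
    labels: OutcomeLabels,
    maternal_score: ScoreSet,
    fetal_score: ScoreSet,
    outcome: str,
    phenotypes: pd.DataFrame,
    cohort_id: str = "",
    use_deciles: bool = True,
    linear_probability: bool = False,
) -> AssocResult:
    """Maternal FG/SBP score model, adjusted for the fetal birth-weight score
    plus sex and gestational age."""
    first, _ = fit_joint(
        labels,
        maternal_score,
        fetal_score,
        outcome,
        phenotypes=phenotypes,
        covariates=["sex", "gestational_age"],
        cohort_id=cohort_id,
        use_deciles=use_deciles,
        linear_probability=linear_probability,
    )
    return first


def meta_fixed(results: list[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effect pool of per-cohort estimates."""
    if len(results) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    roles = {r.score_role for r in results}
    outcomes = {r.outcome for r in results}
    if len(roles) > 1 or len(outcomes) > 1:
        raise ValueError(
            f"inputs mix score roles {sorted(roles)} or outcomes {sorted(outcomes)}"
        )
    betas = np.array([r.beta for r in results], dtype=float)
    ses = np.array([r.se for r in results], dtype=float)
    w = 1.0 / ses**2  # se = inf contributes zero weight
    if w.sum() <= 0:
        raise ValueError("all studies have zero weight")
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (betas - pooled) ** 2))
    return MetaResult(
        score_role=roles.pop(),
        outcome=outcomes.pop(),
        pooled_beta=pooled,
        pooled_se=pooled_se,
        q_stat=q,
        q_df=len(results) - 1,
        n_studies=len(results),
    )


def results_to_frame(
    results: list[AssocResult], meta: list[MetaResult] | None = None
) -> pd.DataFrame:
    """Tidy table: one row per score x outcome x cohort plus pooled rows."""
    rows = []
    for r in results:
        rows.append(
            {
                "score_role": r.score_role,
                "outcome": r.outcome,
                "cohort_id": r.cohort_id,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "adjusted_for": ",".join(r.adjusted_for),
            }
        )
    for m in meta or []:
        rows.append(
            {
                "score_role": m.score_role,
                "outcome": m.outcome,
                "cohort_id": "POOLED",
                "beta": m.pooled_beta,
                "se": m.pooled_se,
                "or": m.pooled_or,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "p": m.p,
                "q_stat": m.q_stat,
                "q_df": m.q_df,
                "q_p": m.q_p,
            }
        )
    return pd.DataFrame(rows)
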