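"""Birth-weight z-scores and SGA/LGA/AGA classification.

Raw birth weights are converted to sex- and gestational-age-adjusted z-scores
either against an external growth reference (mean/SD or LMS rows per sex and
completed week) or by the within-cohort route: regress birth weight on sex
and gestational age among term births and standardize the residuals.

Small- and large-for-gestational-age are defined primarily by the z-score
thresholds z <= -1.28 (SGA) and z >= 1.28 (LGA) — the ~10th and ~90th
centiles of a normal distribution — with a sensitivity definition taking the
lowest and highest 10% of the within-cohort z distribution.  Controls are
either all non-cases for that outcome ("complement") or only
appropriate-for-gestational-age babies between the two cut-offs ("aga_only").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SGA_Z", "LGA_Z",
    "ZScoreTable", "OutcomeLabels",
    "filter_term",
    "zscore_external", "zscore_within_cohort",
    "classify", "case_control",
]

SGA_Z = -1.28
LGA_Z = 1.28
TERM_GA_WEEKS = 37


@dataclass
class ZScoreTable:
    individual_id: np.ndarray
    bw_z: np.ndarray
    method: Literal["external_reference", "within_cohort_residual"]

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.bw_z = np.asarray(self.bw_z, dtype=float)
        if not np.all(np.isfinite(self.bw_z)):
            raise ValueError("z-scores must be finite")

    @property
    def n(self) -> int:
        return len(self.bw_z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": self.individual_id, "bw_z": self.bw_z, "method": self.method}
        )


@dataclass
class OutcomeLabels:
    individual_id: np.ndarray
    label: np.ndarray  # of {"SGA", "LGA", "AGA"}
    control_scheme: Literal["complement", "aga_only"]

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        bad = set(self.label) - {"SGA", "LGA", "AGA"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.control_scheme not in ("complement", "aga_only"):
            raise ValueError("control_scheme must be 'complement' or 'aga_only'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "label": self.label,
                "control_scheme": self.control_scheme,
            }
        )


def filter_term(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Keep term births (gestational age >= 37 completed weeks)."""
    return phenotypes[phenotypes["gestational_age_wk"] >= TERM_GA_WEEKS].reset_index(
        drop=True
    )


def zscore_external(
    phenotypes: pd.DataFrame, reference: pd.DataFrame
) -> ZScoreTable:
    """z-scores against an external sex x gestational-age growth reference.

    ``reference`` carries one row per (sex, ga_weeks) with either ``mean_g``
    and ``sd_g`` columns (z = (bw - mean)/sd) or LMS columns ``L``, ``M``,
    ``S`` (z = ((bw/M)^L - 1)/(L*S); L = 0 degenerates to ln(bw/M)/S).
    """
    lms = {"L", "M", "S"}.issubset(reference.columns)
    if not lms and not {"mean_g", "sd_g"}.issubset(reference.columns):
        raise ValueError("reference needs mean_g/sd_g or L/M/S columns")
    merged = phenotypes.merge(reference, on=["sex", "gestational_age_wk"], how="left")
    key_col = "M" if lms else "mean_g"
    missing = merged[key_col].isna()
    if missing.any():
        combos = sorted(
            set(
                zip(
                    merged.loc[missing, "sex"],
                    merged.loc[missing, "gestational_age_wk"],
                )
            )
        )
        raise ValueError(f"reference rows missing for (sex, GA): {combos}")
    bw = merged["birth_weight_g"].to_numpy(dtype=float)
    if lms:
        L = merged["L"].to_numpy(dtype=float)
        M = merged["M"].to_numpy(dtype=float)
        S = merged["S"].to_numpy(dtype=float)
        if np.any(M <= 0) or np.any(S <= 0):
            raise ValueError("LMS reference requires M > 0 and S > 0")
        with np.errstate(divide="ignore"):
            z = np.where(
                L == 0,
                np.log(bw / M) / S,
                ((bw / M) ** np.where(L == 0, 1.0, L) - 1) / (np.where(L == 0, 1.0, L) * S),
            )
    else:
        sd = merged["sd_g"].to_numpy(dtype=float)
        if np.any(sd <= 0):
            raise ValueError("reference sd_g must be > 0")
        z = (bw - merged["mean_g"].to_numpy(dtype=float)) / sd
    return ZScoreTable(
        individual_id=phenotypes["individual_id"].to_numpy(dtype=object),
        bw_z=z,
        method="external_reference",
    )


def zscore_within_cohort(
    phenotypes: pd.DataFrame, quadratic_ga: bool = False
) -> ZScoreTable:
    """Standardized residuals of birth weight on sex and gestational age.

    Ordinary least squares of ``birth_weight_g`` on a sex indicator and
    (linear, optionally quadratic) gestational age among term births; z is
    the residual divided by the residual SD.  Invariant to affine changes of
    the birth-weight or GA units.
    """
    phen = filter_term(phenotypes)
    n = len(phen)
    if n < 30:
        raise ValueError(f"within-cohort z-scores need >= 30 term births, got {n}")
    sex = phen["sex"].to_numpy(dtype=object)
    if len(set(sex)) < 2:
        raise ValueError("within-cohort regression needs both sexes present")
    ga = phen["gestational_age_wk"].to_numpy(dtype=float)
    if np.all(ga == ga[0]):
        raise ValueError("gestational age is constant; design is rank deficient")
    bw = phen["birth_weight_g"].to_numpy(dtype=float)
    cols = [np.ones(n), (sex == "male").astype(float), ga]
    if quadratic_ga:
        cols.append(ga**2)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, bw, rcond=None)
    resid = bw - X @ coef
    dof = n - X.shape[1]
    sd = float(np.sqrt(resid @ resid / dof))
    if sd <= 1e-8 * max(1.0, float(np.abs(bw).mean())):
        raise ValueError("zero residual variance; z-scores are degenerate")
    return ZScoreTable(
        individual_id=phen["individual_id"].to_numpy(dtype=object),
        bw_z=resid / sd,
        method="within_cohort_residual",
    )


def classify(
    z: ZScoreTable,
    scheme: Literal["threshold_1_28", "cohort_decile_tails"] = "threshold_1_28",
    control_scheme: Literal["complement", "aga_only"] = "complement",
) -> OutcomeLabels:
    """Label individuals SGA / LGA / AGA.

    ``threshold_1_28``: SGA iff z <= -1.28 and LGA iff z >= 1.28 (both
    boundaries inclusive).  ``cohort_decile_tails``: the lowest and highest
    10% of the within-cohort z distribution (floor(n/10) individuals each),
    ties at the boundary broken deterministically by individual ID.
    """
    zz = z.bw_z
    n = z.n
    label = np.full(n, "AGA", dtype=object)
    if scheme == "threshold_1_28":
        label[zz <= SGA_Z] = "SGA"
        label[zz >= LGA_Z] = "LGA"
    elif scheme == "cohort_decile_tails":
        k = n // 10
        if k < 1:
            raise ValueError("cohort-tail scheme needs at least 10 individuals")
        order = np.lexsort((z.individual_id, zz))
        label[order[:k]] = "SGA"
        label[order[n - k:]] = "LGA"
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return OutcomeLabels(
        individual_id=z.individual_id, label=label, control_scheme=control_scheme
    )


def case_control(
    labels: OutcomeLabels, outcome: Literal["SGA", "LGA"]
) -> tuple[np.ndarray, np.ndarray]:
    """Binary outcome vector and inclusion mask for one case definition.

    Returns ``(y, include)`` over all individuals: cases are 1; controls are
    the complement of the case set, or only AGA babies under ``aga_only``;
    everyone else is masked out.
    """
    if outcome not in ("SGA", "LGA"):
        raise ValueError("outcome must be 'SGA' or 'LGA'")
    is_case = labels.label == outcome
    if labels.control_scheme == "complement":
        include = np.ones(len(is_case), dtype=bool)
    else:
        include = is_case | (labels.label == "AGA")
    return is_case.astype(int), include
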