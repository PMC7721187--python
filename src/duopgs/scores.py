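"""Weighted allele scores, maternal/fetal effect separation, deciles.

The genetic score for an individual with dosages g_i and per-allele weights
w_i over N scored SNPs is

    GS = N * (sum_i w_i g_i) / (sum_i w_i)

i.e. a weighted allele count rescaled so that equal weights reduce it to the
raw allele count.  The denominator is only meaningful when all weights share
a sign, so variants with negative weights are flipped to the score-raising
allele (w -> -w, g -> 2 - g) before scoring.

Because mother and child share half their alleles (duo dosage correlation
0.5), marginal GWAS estimates mix the direct fetal and indirect maternal
effects:

    E[b_child]  = bF + 0.5 * bM
    E[b_mother] = bM + 0.5 * bF

``wlm_adjust`` inverts this 2x2 system to recover the independent effects,
bF = (4 b_child - 2 b_mother) / 3 and symmetrically for bM — the weighted
linear model separation used to build independent maternal and fetal score
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import SnpPanel

__all__ = [
    "ScoreSet",
    "EffectPair",
    "compute_gs",
    "duo_marginal_expectation",
    "wlm_adjust",
    "to_deciles",
]

ROLES = ("fetal", "maternal", "fg", "sbp")

MISSING_FLAG_THRESHOLD = 0.05


@dataclass
class ScoreSet:
    """Per-individual genetic score values and (optionally) their deciles."""

    individual_id: np.ndarray
    score: np.ndarray
    score_role: str
    decile: np.ndarray | None = None
    flagged_missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.score = np.asarray(self.score, dtype=float)
        if self.score_role not in ROLES:
            raise ValueError(f"score_role must be one of {ROLES}")
        if len(self.individual_id) != len(self.score):
            raise ValueError("individual_id and score lengths differ")
        if self.decile is not None:
            self.decile = np.asarray(self.decile, dtype=int)
            if np.any((self.decile < 1) | (self.decile > 10)):
                raise ValueError("deciles must lie in 1..10")

    @property
    def n(self) -> int:
        return len(self.score)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"individual_id": self.individual_id, "score": self.score}
        )
        df["score_role"] = self.score_role
        if self.decile is not None:
            df["decile"] = self.decile
        return df


@dataclass
class EffectPair:
    """Marginal child/mother GWAS estimates and their adjusted counterparts.

    Arrays are accepted so a whole panel can be adjusted at once.
    """

    beta_child_marginal: np.ndarray
    beta_mother_marginal: np.ndarray
    se_child: np.ndarray | None = None
    se_mother: np.ndarray | None = None
    beta_fetal_adj: np.ndarray | None = None
    beta_maternal_adj: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_child_marginal = np.atleast_1d(
            np.asarray(self.beta_child_marginal, dtype=float)
        )
        self.beta_mother_marginal = np.atleast_1d(
            np.asarray(self.beta_mother_marginal, dtype=float)
        )
        for name in ("se_child", "se_mother"):
            se = getattr(self, name)
            if se is not None:
                se = np.atleast_1d(np.asarray(se, dtype=float))
                if np.any(se <= 0):
                    raise ValueError(f"{name} must be > 0")
                setattr(self, name, se)


def _oriented(
    dosages: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip negative-weight variants to the score-raising allele."""
    flip = weights < 0
    if not np.any(flip):
        return dosages, weights, flip
    g = dosages.copy()
    g[:, flip] = 2.0 - g[:, flip]
    return g, np.abs(weights), flip


def compute_gs(
    cohort_dosages: np.ndarray,
    panel: SnpPanel,
    role: str,
    individual_id: np.ndarray | None = None,
    orient: str = "auto",
) -> ScoreSet:
    """Evaluate GS = N * sum(w g) / sum(w) for every individual.

    ``orient="auto"`` flips variants whose weight for this role is negative;
    ``orient="strict"`` rejects them instead.  Missing dosages (NaN) are
    dropped per individual from numerator, denominator and the N factor, so
    the score keeps its scale under sporadic missingness; individuals missing
    more than 5% of panel SNPs are flagged.
    """
    g = np.asarray(cohort_dosages, dtype=float)
    if g.ndim != 2 or g.shape[1] != panel.n_snps:
        raise ValueError(
            f"dosage matrix has {g.shape[1] if g.ndim == 2 else '?'} columns, "
            f"panel has {panel.n_snps} SNPs"
        )
    w = panel.weights(role)
    if np.all(w == 0):
        raise ValueError("all score weights are zero")
    if orient == "strict":
        if np.any(w < 0):
            bad = list(panel.variant_id[w < 0])
            raise ValueError(f"negative weights (orientation mismatch) for: {bad}")
    elif orient == "auto":
        g, w, _ = _oriented(g, w)
    else:
        raise ValueError("orient must be 'auto' or 'strict'")
    valid = np.isfinite(g)
    n_valid = valid.sum(axis=1)
    if np.any(n_valid == 0):
        raise ValueError("some individuals have no non-missing dosages")
    g_filled = np.where(valid, g, 0.0)
    num = g_filled @ w
    denom = valid @ w
    if np.any(denom <= 0):
        raise ValueError("sum of weights over non-missing SNPs must be positive")
    score = n_valid * num / denom
    flagged = (1 - n_valid / panel.n_snps) > MISSING_FLAG_THRESHOLD
    if individual_id is None:
        individual_id = np.array(
            [f"ind{i + 1}" for i in range(g.shape[0])], dtype=object
        )
    return ScoreSet(
        individual_id=individual_id,
        score=score,
        score_role=role,
        flagged_missing=flagged,
    )


def duo_marginal_expectation(
    beta_fetal: np.ndarray, beta_maternal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward map: expected marginal estimates given independent effects."""
    bf = np.asarray(beta_fetal, dtype=float)
    bm = np.asarray(beta_maternal, dtype=float)
    return bf + 0.5 * bm, bm + 0.5 * bf


def wlm_adjust(pair: EffectPair) -> EffectPair:
    """Solve the duo expectation system for the independent effects.

    The unique solution of E[b_child] = bF + bM/2, E[b_mother] = bM + bF/2:

        bF = (4 b_child - 2 b_mother) / 3
        bM = (4 b_mother - 2 b_child) / 3
    """
    bc = pair.beta_child_marginal
    bm = pair.beta_mother_marginal
    return replace(
        pair,
        beta_fetal_adj=(4 * bc - 2 * bm) / 3,
        beta_maternal_adj=(4 * bm - 2 * bc) / 3,
    )


def to_deciles(scores: ScoreSet) -> ScoreSet:
    """Assign within-cohort score deciles 1..10 by fixed-size rank blocks.

    Individuals are stably sorted by score (input order breaks ties), then cut
    into ten blocks whose sizes differ by at most one.  Requires at least 10
    individuals and a non-degenerate score distribution.
    """
    n = scores.n
    if n < 10:
        raise ValueError("decile assignment requires at least 10 individuals")
    s = scores.score
    if np.all(s == s[0]):
        raise ValueError("all scores identical; decile assignment is degenerate")
    order = np.argsort(s, kind="stable")
    decile = np.empty(n, dtype=int)
    decile[order] = np.floor(np.arange(n) * 10 / n).astype(int) + 1
    return replace(scores, decile=decile)
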