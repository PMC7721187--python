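"""Simulation test for deviation from an additive polygenic model.

The question: across bins of the birth-weight distribution, is the mean
genetic score of the babies in each bin what an additive polygenic model
predicts?  Under that model an individual's standardized phenotype is

    p_s = x_s + GS_s,        x_s ~ N(0, 1 - sum_i sigma2_SNP_i)

where GS_s is the weighted score built from the within-cohort conditional
per-SNP effects (each member's effect adjusted for the other duo member's
genotype at the same SNP) and sigma2_SNP_i = 2 f_i (1 - f_i) beta_i^2 is the
variance explained by SNP i under HWE on the unit-variance phenotype scale.

The null distribution of per-bin mean standardized GS is built by Monte
Carlo: simulate genotypes at the observed frequencies, form GS_s and p_s,
standardize GS within each replicate, bin individuals by phenotype
quantile, and record each bin's mean.  By default each replicate is a full
mother-child duo that re-estimates its own conditional weights before
scoring (with noise-debiased weights used for generation), so the null
carries the same estimation noise as the observed statistic; see
``simulate_null`` for why the fixed-weight alternative is anticonservative.
The observed bin means (same binning, real phenotypes) are ranked against
the null to give an empirical p value per bin; per-cohort p values are
combined by a sqrt(n)-weighted Stouffer z method.

A deficit of genetic smallness in the lowest bins — babies lighter than
their common-variant score predicts — shows up as an observed bin mean
*above* the null envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import ZScoreTable
from .simulate import DuoCohort

__all__ = [
    "ConditionalBetas",
    "BinSpec",
    "DeviationResult",
    "conditional_betas",
    "observed_bin_means",
    "simulate_null",
    "empirical_p",
    "meta_p",
    "run_deviation_test",
    "deviation_to_frame",
]

DEFAULT_N_SIMS = 10_000


@dataclass
class ConditionalBetas:
    """Within-cohort per-SNP effects adjusted for the other duo member."""

    variant_id: np.ndarray
    beta_cond: np.ndarray
    freq_obs: np.ndarray
    member: str  # which member's effects these are: "fetal" or "maternal"
    se_cond: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.beta_cond = np.asarray(self.beta_cond, dtype=float)
        self.freq_obs = np.asarray(self.freq_obs, dtype=float)
        if self.se_cond is not None:
            self.se_cond = np.asarray(self.se_cond, dtype=float)
        if np.any((self.freq_obs <= 0) | (self.freq_obs >= 1)):
            raise ValueError("observed frequencies must lie strictly in (0, 1)")

    @property
    def var_explained(self) -> np.ndarray:
        """sigma2_SNP_i = 2 f (1 - f) beta^2 on the unit-variance scale."""
        return 2 * self.freq_obs * (1 - self.freq_obs) * self.beta_cond**2

    @property
    def total_var(self) -> float:
        return float(self.var_explained.sum())

    def shrunk_betas(self) -> np.ndarray:
        """Noise-debiased effects for generating parametric-bootstrap data.

        E[beta_hat^2] = beta^2 + se^2, so the raw estimates overstate the
        panel's variance by ~ sum(2f(1-f) se^2); a global shrinkage factor
        restores the unbiased total while preserving the effect pattern.
        Without stored SEs the estimates are returned unshrunk.
        """
        if self.se_cond is None:
            return self.beta_cond
        het = 2 * self.freq_obs * (1 - self.freq_obs)
        noise = float(np.sum(het * self.se_cond**2))
        total = self.total_var
        if total <= 0:
            return self.beta_cond
        c = np.sqrt(max(total - noise, 0.0) / total)
        return c * self.beta_cond


@dataclass
class BinSpec:
    """Phenotype-quantile bins of a given percent width.

    ``anchor="lower"`` lays bins from the bottom of the distribution
    (0-3, 3-6, ...); ``anchor="upper"`` from the top (..., 94-97, 97-100),
    leaving any short remainder bin at the opposite end.
    """

    width_percent: float = 10.0
    anchor: str = "lower"
    edges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.width_percent <= 50:
            raise ValueError("bin width must lie in (0, 50] percent")
        if self.anchor not in ("lower", "upper"):
            raise ValueError("anchor must be 'lower' or 'upper'")
        w = self.width_percent / 100.0
        cuts = np.arange(0.0, 1.0, w)
        if self.anchor == "upper":
            cuts = np.sort(1.0 - cuts)
            edges = np.concatenate([[0.0], cuts]) if cuts[0] > 0 else cuts
        else:
            edges = np.concatenate([cuts, [1.0]]) if cuts[-1] < 1 else np.append(cuts, 1.0)
        edges = np.unique(np.round(np.clip(edges, 0.0, 1.0), 9))
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("degenerate bin edges")
        self.edges = edges

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        return [
            f"{100 * lo:g}-{100 * hi:g}%"
            for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]

    def counts(self, n: int) -> np.ndarray:
        """Individuals per bin when n are ranked and cut at the edges."""
        bounds = np.round(self.edges * n).astype(int)
        return np.diff(bounds)

    def assign(self, values: np.ndarray, tiebreak: np.ndarray | None = None) -> np.ndarray:
        """Bin index per individual from within-sample quantile rank."""
        n = len(values)
        counts = self.counts(n)
        if np.any(counts <= 0):
            raise ValueError(
                f"empty phenotype bin at n={n}; need at least "
                f"{int(np.ceil(1 / np.min(np.diff(self.edges))))} individuals"
            )
        if tiebreak is None:
            order = np.argsort(values, kind="stable")
        else:
            order = np.lexsort((tiebreak, values))
        idx = np.empty(n, dtype=int)
        idx[order] = np.repeat(np.arange(self.n_bins), counts)
        return idx


@dataclass
class DeviationResult:
    """Observed vs simulated bin-mean GS for one phenotype bin."""

    bin_label: str
    observed_mean: float
    null_mean: float
    null_lo95: float
    null_hi95: float
    p_emp: float
    n_sims: int
    cohort_id: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.null_lo95 <= self.null_mean <= self.null_hi95):
            raise ValueError("null envelope must bracket the null mean")
        if not 0 < self.p_emp <= 1:
            raise ValueError("empirical p must lie in (0, 1]")


def conditional_betas(
    duos: DuoCohort, z: ZScoreTable, member: str = "fetal"
) -> ConditionalBetas:
    """Per-SNP OLS of bw_z on one member's dosage adjusted for the other's.

    For each SNP the model is z ~ 1 + g_member + g_other (both duo members at
    the same variant); ``beta_cond`` is the member's coefficient.  Monomorphic
    SNPs get beta 0 (zero variance explained) with a warning.
    """
    if member not in ("fetal", "maternal"):
        raise ValueError("member must be 'fetal' or 'maternal'")
    if duos.g_maternal is None:
        raise ValueError("conditional analysis requires both duo genotype matrices")
    g_self = duos.g_fetal if member == "fetal" else duos.g_maternal
    g_other = duos.g_maternal if member == "fetal" else duos.g_fetal
    if len(z.bw_z) != duos.n:
        raise ValueError("z-score table does not match cohort size")
    y = z.bw_z - z.bw_z.mean()
    n, m = g_self.shape
    a = g_self - g_self.mean(axis=0)
    b = g_other - g_other.mean(axis=0)
    # closed-form 2-covariate OLS per SNP (intercept absorbed by centering)
    saa = np.einsum("ij,ij->j", a, a)
    sbb = np.einsum("ij,ij->j", b, b)
    sab = np.einsum("ij,ij->j", a, b)
    say = a.T @ y
    sby = b.T @ y
    det = saa * sbb - sab**2
    mono = (saa == 0) | (det <= 0)
    if np.any(mono):
        warnings.warn(
            f"{int(mono.sum())} monomorphic/degenerate SNPs set to zero effect",
            stacklevel=2,
        )
    beta = np.zeros(m)
    ok = ~mono
    beta[ok] = (sbb[ok] * say[ok] - sab[ok] * sby[ok]) / det[ok]
    # Wald SE of the member's coefficient: sigma_j^2 * [(X'X)^-1]_11
    beta_other = np.zeros(m)
    beta_other[ok] = (saa[ok] * sby[ok] - sab[ok] * say[ok]) / det[ok]
    syy = float(y @ y)
    rss = np.maximum(syy - beta * say - beta_other * sby, 0.0)
    se = np.zeros(m)
    se[ok] = np.sqrt(rss[ok] / max(n - 3, 1) * sbb[ok] / det[ok])
    freq = g_self.mean(axis=0) / 2.0
    freq = np.clip(freq, 1e-6, 1 - 1e-6)
    variant_id = np.array([f"snp{j + 1}" for j in range(m)], dtype=object)
    return ConditionalBetas(
        variant_id=variant_id, beta_cond=beta, freq_obs=freq, member=member,
        se_cond=se,
    )


def observed_bin_means(
    scores: np.ndarray,
    z: ZScoreTable,
    bins: BinSpec,
) -> np.ndarray:
    """Mean standardized GS per within-cohort phenotype-quantile bin.

    ``scores`` are raw GS values aligned to ``z``; they are standardized to
    mean 0 / SD 1 within the cohort before averaging, so results are
    invariant to the score's scale and location.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) != z.n:
        raise ValueError("scores and z-scores must cover the same individuals")
    sd = s.std()
    if sd == 0:
        raise ValueError("degenerate score distribution")
    s_std = (s - s.mean()) / sd
    idx = bins.assign(z.bw_z, tiebreak=z.individual_id)
    sums = np.bincount(idx, weights=s_std, minlength=bins.n_bins)
    counts = np.bincount(idx, minlength=bins.n_bins)
    return sums / counts


def simulate_null(
    betas: ConditionalBetas,
    n_individuals: int,
    n_sims: int = DEFAULT_N_SIMS,
    bins: BinSpec | None = None,
    seed: int | None = None,
    reestimate: bool = True,
    max_chunk_elements: int = 12_000_000,
) -> np.ndarray:
    """Null matrix (n_sims x n_bins) of bin-mean standardized GS.

    Each replicate draws genotypes at the observed frequencies, forms the
    centered score GS = sum beta_i (g_i - 2 f_i), draws
    x ~ N(0, 1 - sum sigma2_SNP_i) and the phenotype p = x + GS,
    standardizes the score within the replicate, bins individuals by
    phenotype rank and records each bin's mean.

    With ``reestimate=True`` (default) every replicate simulates a full
    mother-child duo and re-derives the conditional per-SNP weights from its
    own data before scoring — the parametric-bootstrap form, which mirrors
    the estimation noise the observed statistic carries.  Scoring each
    replicate with the fixed observed weights (``reestimate=False``) treats
    those noisy estimates as true effects and makes the null's
    score-phenotype relation systematically steeper than the observed one,
    an anticonservative bias of order m/(3n) in the score-phenotype
    covariance that is visible whenever the panel is not small relative to
    the cohort.  Replicates are vectorized in chunks; the genotype block
    runs in float32 (dosages are exact small integers; the ~1e-7 score
    error is far below Monte-Carlo noise).
    """
    bins = bins or BinSpec()
    total_var = betas.total_var
    if total_var >= 1:
        raise ValueError(
            f"total variance explained {total_var:.3f} >= 1; negative residual "
            "variance — conditional effects are implausibly large"
        )
    if n_sims < 1 or n_individuals < 1:
        raise ValueError("n_sims and n_individuals must be >= 1")
    counts = bins.counts(n_individuals)
    if np.any(counts <= 0):
        raise ValueError("empty phenotype bin; increase n_individuals")
    rng = np.random.default_rng(seed)
    n = n_individuals
    f = betas.freq_obs
    # bootstrap generation uses noise-debiased weights so the simulated
    # panel explains the estimated (not noise-inflated) share of variance;
    # the printed fixed-weight variant keeps the raw estimates
    beta = betas.shrunk_betas() if reestimate else betas.beta_cond
    m = len(f)
    het = 2 * f * (1 - f)
    resid_sd = np.sqrt(1.0 - float(np.sum(het * beta**2)))
    # 16-bit inverse-CDF genotype sampling: cell probabilities quantized to
    # 2^-16, far below Monte-Carlo noise, and ~3x faster than float draws
    q0_16 = np.round((1 - f) ** 2 * 65536).astype(np.uint16)
    q01_16 = np.round(((1 - f) ** 2 + 2 * f * (1 - f)) * 65536).astype(np.uint16)
    f_16 = np.round(f * 65536).astype(np.uint16)
    beta32 = beta.astype(np.float32)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    chunk = max(1, int(max_chunk_elements // (n * m)))
    null = np.empty((n_sims, bins.n_bins))
    done = 0
    while done < n_sims:
        s = min(chunk, n_sims - done)
        u = rng.integers(0, 65536, size=(s, n, m), dtype=np.uint16)
        hwe = (u >= q0_16).astype(np.uint8) + (u >= q01_16)
        del u
        if reestimate:
            # mother under HWE, child by Mendelian transmission, so the
            # within-replicate conditional fit sees the duo correlation
            u2 = rng.integers(0, 65536, size=(s, n, m), dtype=np.uint16)
            transmitted = (hwe == 2) | ((hwe == 1) & (u2 < 32768))
            u3 = rng.integers(0, 65536, size=(s, n, m), dtype=np.uint16)
            g_self = transmitted.astype(np.float32) + (u3 < f_16)
            g_other = hwe.astype(np.float32)
            del u2, u3, transmitted, hwe
        else:
            g_self = hwe.astype(np.float32)
            del hwe
        a = g_self - g_self.mean(axis=1, keepdims=True)
        gs_true = (a @ beta32).astype(np.float64)
        x = rng.normal(0.0, resid_sd, size=(s, n))
        p = x + gs_true
        if reestimate:
            b = g_other - g_other.mean(axis=1, keepdims=True)
            y32 = (p - p.mean(axis=1, keepdims=True)).astype(np.float32)
            saa = np.einsum("snm,snm->sm", a, a)
            sbb = np.einsum("snm,snm->sm", b, b)
            sab = np.einsum("snm,snm->sm", a, b)
            say = np.einsum("snm,sn->sm", a, y32)
            sby = np.einsum("snm,sn->sm", b, y32)
            det = saa * sbb - sab**2
            ok = det > 0
            beta_rep = np.zeros((s, m), dtype=np.float32)
            beta_rep[ok] = (sbb[ok] * say[ok] - sab[ok] * sby[ok]) / det[ok]
            gs = np.einsum("snm,sm->sn", a, beta_rep).astype(np.float64)
            del b, y32
        else:
            gs = gs_true
        del a, g_self
        if reestimate:
            del g_other
        sd = gs.std(axis=1, keepdims=True)
        gs_std = (gs - gs.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
        order = np.argsort(p, axis=1)
        sorted_gs = np.take_along_axis(gs_std, order, axis=1)
        sums = np.add.reduceat(sorted_gs, starts, axis=1)
        null[done : done + s] = sums / counts
        done += s
    return null


def empirical_p(
    observed: np.ndarray,
    null: np.ndarray,
    bins: BinSpec,
    cohort_id: str = "",
    n: int = 0,
    two_sided: bool = True,
) -> list[DeviationResult]:
    """Rank the observed bin means within the simulated null.

    Two-sided (default): p = min(1, 2 * (min(a, b) + 1) / (n_sims + 1)) with
    a = #{null <= obs}, b = #{null >= obs}.  One-sided uses the upper tail
    (observed above null), the direction of a tail whose scores exceed what
    birth weight predicts.
    """
    observed = np.asarray(observed, dtype=float)
    n_sims, n_bins = null.shape
    if len(observed) != n_bins or n_bins != bins.n_bins:
        raise ValueError("observed/null/bins dimensions disagree")
    a = (null <= observed).sum(axis=0)
    b = (null >= observed).sum(axis=0)
    if two_sided:
        p = np.minimum(1.0, 2.0 * (np.minimum(a, b) + 1) / (n_sims + 1))
    else:
        p = (b + 1) / (n_sims + 1)
    lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
    mean = null.mean(axis=0)
    return [
        DeviationResult(
            bin_label=bins.labels[j],
            observed_mean=float(observed[j]),
            null_mean=float(mean[j]),
            null_lo95=float(lo[j]),
            null_hi95=float(hi[j]),
            p_emp=float(p[j]),
            n_sims=n_sims,
            cohort_id=cohort_id,
            n=n,
        )
        for j in range(n_bins)
    ]


def meta_p(
    per_cohort: list[list[DeviationResult]],
    cohort_sizes: list[int],
) -> pd.DataFrame:
    """Stouffer sqrt(n)-weighted combination of per-cohort empirical p values.

    Each cohort contributes a signed z (sign of observed - null mean,
    magnitude from its two-sided p); Z = sum(w_k z_k)/sqrt(sum w_k^2) with
    w_k = sqrt(n_k), reported with a two-sided p per bin.
    """
    if len(per_cohort) != len(cohort_sizes):
        raise ValueError("need one cohort size per result list")
    labels = [r.bin_label for r in per_cohort[0]]
    for results in per_cohort[1:]:
        if [r.bin_label for r in results] != labels:
            raise ValueError("bin specifications differ across cohorts")
    w = np.sqrt(np.asarray(cohort_sizes, dtype=float))
    rows = []
    for j, label in enumerate(labels):
        zs = []
        for results in per_cohort:
            r = results[j]
            # cap z at the resolution of the empirical p
            p_in = max(min(r.p_emp, 1.0), 1.0 / (r.n_sims + 1))
            mag = stats.norm.isf(p_in / 2)
            sign = np.sign(r.observed_mean - r.null_mean) or 1.0
            zs.append(sign * mag)
        zs = np.asarray(zs)
        z_comb = float(np.sum(w * zs) / np.sqrt(np.sum(w**2)))
        rows.append(
            {
                "bin": label,
                "z_combined": z_comb,
                "p_combined": float(2 * stats.norm.sf(abs(z_comb))),
                "n_cohorts": len(per_cohort),
            }
        )
    return pd.DataFrame(rows)


def run_deviation_test(
    duos: DuoCohort,
    z: ZScoreTable,
    member: str = "fetal",
    bins: BinSpec | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | None = None,
    two_sided: bool = True,
    reestimate: bool = True,
) -> list[DeviationResult]:
    """End-to-end deviation test for one cohort and duo member.

    Estimates conditional per-SNP effects, builds the observed score with
    those effects as weights, computes observed bin means against the
    within-cohort phenotype ranks, simulates the additive-model null and
    returns per-bin results.
    """
    bins = bins or BinSpec()
    cb = conditional_betas(duos, z, member=member)
    g = duos.g_fetal if member == "fetal" else duos.g_maternal
    raw = (g - 2 * cb.freq_obs) @ cb.beta_cond
    observed = observed_bin_means(raw, z, bins)
    null = simulate_null(
        cb, duos.n, n_sims=n_sims, bins=bins, seed=seed, reestimate=reestimate
    )
    return empirical_p(
        observed, null, bins, cohort_id=duos.cohort_id, n=duos.n, two_sided=two_sided
    )


def plot_deviation(results: list[DeviationResult], ax=None, title: str = ""):
    """Observed bin-mean GS against the simulated null and 95% envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(results))
    ax.plot(xs, [r.null_mean for r in results], "k-", label="simulated null mean")
    ax.plot(xs, [r.null_lo95 for r in results], "k:", label="null 95% envelope")
    ax.plot(xs, [r.null_hi95 for r in results], "k:")
    ax.plot(xs, [r.observed_mean for r in results], "b-", label="observed")
    ax.set_xticks(xs, [r.bin_label for r in results], rotation=45, ha="right")
    ax.set_xlabel("birth weight bin (percentile)")
    ax.set_ylabel("mean standardized GS")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    ax.figure.tight_layout()
    return ax


def deviation_to_frame(results: list[DeviationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": [r.bin_label for r in results],
            "observed_mean": [r.observed_mean for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_lo95": [r.null_lo95 for r in results],
            "null_hi95": [r.null_hi95 for r in results],
            "p_emp": [r.p_emp for r in results],
            "n_sims": [r.n_sims for r in results],
            "cohort_id": [r.cohort_id for r in results],
        }
    )
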