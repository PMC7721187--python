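"""Synthetic mother-child duo cohorts with an additive polygenic birth weight.

Generates the data structures the rest of the package operates on: a panel of
independent biallelic SNPs with maternal and fetal per-allele effects, duo
genotypes under Hardy-Weinberg equilibrium with Mendelian transmission from
mother to child (expected mother-child dosage correlation 0.5 under random
mating), and a standardized birth-weight phenotype built additively from both
genomes plus Gaussian noise.  Optional "contamination" injects tail
individuals whose birth weight is *not* explained by their common-variant
score — either an environmental deficit applied to a random fraction of
babies, or a rare un-scored large-effect allele — which is the violation of
the additive polygenic model the deviation test is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SnpPanel",
    "DuoCohort",
    "ContaminationSpec",
    "generate_panel",
    "generate_duos",
    "generate_phenotype",
    "generate_cohort",
    "effect_sd_for_variance",
    "write_panel",
    "read_panel",
    "write_cohort",
    "read_cohort",
]

_BASES = ("A", "C", "G", "T")

PANEL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "freq",
    "w_fetal",
    "w_maternal",
    "true_beta_fetal",
    "true_beta_maternal",
]


@dataclass
class SnpPanel:
    """Per-variant metadata: alleles, frequency and score weights.

    ``w_fetal`` / ``w_maternal`` are the per-allele score weights (SD of
    birth weight per effect allele).  ``true_beta_*`` are the generative
    effect sizes used only by the simulator; for panels read from external
    weight tables they are NaN.
    """

    variant_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    freq: np.ndarray
    w_fetal: np.ndarray
    w_maternal: np.ndarray
    true_beta_fetal: np.ndarray | None = None
    true_beta_maternal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.freq = np.asarray(self.freq, dtype=float)
        self.w_fetal = np.asarray(self.w_fetal, dtype=float)
        self.w_maternal = np.asarray(self.w_maternal, dtype=float)
        for name in ("true_beta_fetal", "true_beta_maternal"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.variant_id)
        for name in ("effect_allele", "other_allele", "freq", "w_fetal", "w_maternal"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel column {name!r} has wrong length")
        if len(set(self.variant_id)) != n:
            dupes = pd.Series(self.variant_id)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate variant_id in panel: {dupes}")
        if np.any(self.freq <= 0) or np.any(self.freq >= 1):
            raise ValueError("effect-allele frequencies must lie strictly in (0, 1)")
        same = self.effect_allele == self.other_allele
        if np.any(same):
            bad = list(self.variant_id[same])
            raise ValueError(f"effect and other allele identical for: {bad}")

    @property
    def n_snps(self) -> int:
        return len(self.variant_id)

    def weights(self, role: str) -> np.ndarray:
        """Score weights for a role; fg/sbp panels carry a single weight."""
        if role in ("fetal", "fg", "sbp"):
            return self.w_fetal
        if role == "maternal":
            return self.w_maternal
        raise ValueError(f"unknown score role: {role!r}")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "variant_id": self.variant_id,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "freq": self.freq,
            "w_fetal": self.w_fetal,
            "w_maternal": self.w_maternal,
        }
        if self.true_beta_fetal is not None:
            data["true_beta_fetal"] = self.true_beta_fetal
        if self.true_beta_maternal is not None:
            data["true_beta_maternal"] = self.true_beta_maternal
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpPanel":
        kwargs = {}
        for name in ("true_beta_fetal", "true_beta_maternal"):
            if name in df.columns:
                kwargs[name] = df[name].to_numpy(dtype=float)
        return cls(
            variant_id=df["variant_id"].to_numpy(dtype=object),
            effect_allele=df["effect_allele"].to_numpy(dtype=object),
            other_allele=df["other_allele"].to_numpy(dtype=object),
            freq=df["freq"].to_numpy(dtype=float),
            w_fetal=df["w_fetal"].to_numpy(dtype=float),
            w_maternal=df["w_maternal"].to_numpy(dtype=float),
            **kwargs,
        )


@dataclass
class DuoCohort:
    """Aligned maternal/fetal dosage matrices plus phenotypes for one cohort.

    Row ``i`` of both matrices refers to the same mother-child pair; the SNP
    (column) order matches the generating :class:`SnpPanel`.  ``g_maternal``
    is ``None`` for child-only cohorts.
    """

    cohort_id: str
    g_fetal: np.ndarray
    g_maternal: np.ndarray | None
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.g_fetal = np.asarray(self.g_fetal, dtype=float)
        if self.g_maternal is not None:
            self.g_maternal = np.asarray(self.g_maternal, dtype=float)
            if self.g_maternal.shape != self.g_fetal.shape:
                raise ValueError("maternal and fetal dosage matrices differ in shape")
        for g in (self.g_fetal, self.g_maternal):
            if g is not None and g.size and (np.nanmin(g) < 0 or np.nanmax(g) > 2):
                raise ValueError("dosages must lie within [0, 2]")

    @property
    def n(self) -> int:
        return self.g_fetal.shape[0]

    @property
    def n_snps(self) -> int:
        return self.g_fetal.shape[1]

    @property
    def individual_id(self) -> np.ndarray:
        return self.phenotypes["individual_id"].to_numpy(dtype=object)


@dataclass(frozen=True)
class ContaminationSpec:
    """How to break the additive polygenic model in a fraction of babies.

    ``environmental`` subtracts ``shift_sd`` (SD units) from a random
    ``fraction`` of babies; ``rare_variant`` assigns carrier status for an
    un-scored allele at frequency ``rare_freq`` and subtracts ``rare_beta``
    per carried allele.
    """

    mode: Literal["none", "environmental", "rare_variant"] = "none"
    fraction: float = 0.0
    shift_sd: float = 0.0
    rare_freq: float = 0.0
    rare_beta: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "environmental", "rare_variant"):
            raise ValueError(f"unknown contamination mode: {self.mode!r}")
        if self.mode == "environmental" and not (0 < self.fraction < 0.5):
            raise ValueError("environmental contamination fraction must be in (0, 0.5)")
        if self.mode == "rare_variant" and not (0 < self.rare_freq < 0.5):
            raise ValueError("rare_freq must be in (0, 0.5)")
        if not np.isfinite([self.shift_sd, self.rare_beta]).all():
            raise ValueError("shift_sd and rare_beta must be finite")


def effect_sd_for_variance(
    target_variance: float,
    n_snps: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Per-SNP effect-size SD giving an expected total fetal variance.

    With frequencies uniform on ``freq_range`` and effects ~ N(0, sd^2), the
    expected fetal genetic variance is ``n_snps * E[2f(1-f)] * sd^2``; invert
    that for ``sd``.  Useful to emulate a panel explaining, say, 7% of the
    phenotype variance.
    """
    lo, hi = freq_range
    # E[f(1-f)] for f ~ U(lo, hi): E[f] - E[f^2]
    mean_f = (lo + hi) / 2
    mean_f2 = (hi**3 - lo**3) / (3 * (hi - lo)) if hi > lo else lo**2
    e_het = 2 * (mean_f - mean_f2)
    if e_het <= 0:
        raise ValueError("degenerate frequency range")
    return float(np.sqrt(target_variance / (n_snps * e_het)))


def generate_panel(
    n_snps: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
    effect_sd: float = 0.02,
    maternal_fetal_corr: float = 0.0,
    seed: int | None = None,
) -> SnpPanel:
    """Draw a panel of independent SNPs with bivariate-normal duo effects.

    Frequencies are uniform on ``freq_range``; (fetal, maternal) true effect
    sizes are bivariate normal with common SD ``effect_sd`` and the given
    correlation.  Score weights default to the true effects, mirroring a
    perfectly estimated external GWAS.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = freq_range
    if not (0 < lo < 1 and 0 < hi < 1 and lo <= hi):
        raise ValueError("freq_range endpoints must lie strictly inside (0, 1)")
    if not -1 <= maternal_fetal_corr <= 1:
        raise ValueError("maternal_fetal_corr must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(lo, hi, size=n_snps)
    # explicit construction (not multivariate_normal) so corr = +/-1 gives
    # exactly equal/opposite effects
    z1, z2 = rng.standard_normal((2, n_snps))
    rho = maternal_fetal_corr
    betas = effect_sd * np.column_stack([z1, rho * z1 + np.sqrt(1 - rho**2) * z2])
    alleles = np.array(
        [rng.choice(4, size=2, replace=False) for _ in range(n_snps)]
    )
    return SnpPanel(
        variant_id=np.array([f"rs{i + 1}" for i in range(n_snps)], dtype=object),
        effect_allele=np.array([_BASES[a] for a in alleles[:, 0]], dtype=object),
        other_allele=np.array([_BASES[a] for a in alleles[:, 1]], dtype=object),
        freq=freq,
        w_fetal=betas[:, 0].copy(),
        w_maternal=betas[:, 1].copy(),
        true_beta_fetal=betas[:, 0].copy(),
        true_beta_maternal=betas[:, 1].copy(),
    )


def generate_duos(
    panel: SnpPanel, n: int, seed: int | None = None, cohort_id: str = "SIM"
) -> DuoCohort:
    """Simulate ``n`` mother-child genotype pairs under HWE and Mendelian
    transmission.

    Maternal genotypes are Binomial(2, f) per SNP.  The child receives one of
    the mother's two alleles uniformly at random plus an independent paternal
    allele ~ Bernoulli(f); the father is never materialized.  SNPs are
    independent (no LD).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    f = panel.freq
    m = panel.n_snps
    g_mat = rng.binomial(2, f, size=(n, m)).astype(float)
    # transmitted allele: Bernoulli(g_m / 2) is the chance a uniformly chosen
    # maternal allele is the effect allele
    transmitted = rng.random((n, m)) < g_mat / 2.0
    paternal = rng.random((n, m)) < f
    g_fet = transmitted.astype(float) + paternal.astype(float)
    ids = np.array([f"{cohort_id}_{i + 1}" for i in range(n)], dtype=object)
    phen = pd.DataFrame({"individual_id": ids, "cohort_id": cohort_id})
    return DuoCohort(cohort_id=cohort_id, g_fetal=g_fet, g_maternal=g_mat, phenotypes=phen)


def generate_phenotype(
    duos: DuoCohort,
    panel: SnpPanel,
    residual_sd: float | None = None,
    contamination: ContaminationSpec | None = None,
    seed: int | None = None,
    mean_g: float = 3500.0,
    sd_g: float = 500.0,
) -> DuoCohort:
    """Fill in a standardized birth weight built from both genomes.

    ``bw_z = sum_i bF_i (g_fetal_i - 2f_i) + sum_i bM_i (g_maternal_i - 2f_i)
    + eps`` with ``eps ~ N(0, residual_sd^2)``.  ``residual_sd=None`` picks the
    value that makes the total phenotype variance 1, accounting for the 0.5
    duo genotype correlation.  Contamination is applied afterwards on the z
    scale.  Gram-scale birth weight is an affine mapping ``mean_g + sd_g *
    bw_z``; sex is Bernoulli(0.5) and gestational age discrete-uniform on
    37..42 completed weeks (term births).
    """
    if panel.true_beta_fetal is None or panel.true_beta_maternal is None:
        raise ValueError("panel has no generative effect sizes (true_beta_*)")
    contamination = contamination or ContaminationSpec()
    rng = np.random.default_rng(seed)
    f = panel.freq
    b_f = panel.true_beta_fetal
    b_m = panel.true_beta_maternal
    het = 2 * f * (1 - f)
    # genetic variance includes the mother-child covariance term
    # cov(g_c, g_m) = f(1-f), i.e. half the HWE variance
    var_g = float(np.sum(het * (b_f**2 + b_m**2 + b_f * b_m)))
    if residual_sd is None:
        if var_g >= 1:
            raise ValueError(
                f"genetic variance {var_g:.3f} >= 1; rescale effect sizes to use "
                "the automatic residual SD"
            )
        residual_sd = float(np.sqrt(1 - var_g))
    if duos.g_maternal is None:
        raise ValueError("phenotype generation requires maternal genotypes")
    gen = (duos.g_fetal - 2 * f) @ b_f + (duos.g_maternal - 2 * f) @ b_m
    bw_z = gen + rng.normal(0.0, residual_sd, size=duos.n)
    bw_z = _contaminate(bw_z, contamination, rng)
    phen = duos.phenotypes.copy()
    phen["bw_z"] = bw_z
    phen["birth_weight_g"] = mean_g + sd_g * bw_z
    phen["sex"] = np.where(rng.random(duos.n) < 0.5, "male", "female")
    phen["gestational_age_wk"] = rng.integers(37, 43, size=duos.n)
    return replace(duos, phenotypes=phen)


def _contaminate(
    bw_z: np.ndarray, spec: ContaminationSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.mode == "none":
        return bw_z
    local = rng if spec.seed is None else np.random.default_rng(spec.seed)
    out = bw_z.copy()
    n = len(out)
    if spec.mode == "environmental":
        k = int(round(spec.fraction * n))
        affected = local.choice(n, size=k, replace=False)
        out[affected] -= spec.shift_sd
    else:  # rare_variant
        carriers = local.binomial(2, spec.rare_freq, size=n)
        out -= spec.rare_beta * carriers
    return out


def generate_cohort(
    panel: SnpPanel,
    n: int,
    seed: int | None = None,
    cohort_id: str = "SIM",
    residual_sd: float | None = None,
    contamination: ContaminationSpec | None = None,
) -> DuoCohort:
    """Genotypes plus phenotype in one call, with independent substreams."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    ss = seed.spawn(2)
    duos = generate_duos(panel, n, seed=ss[0], cohort_id=cohort_id)
    return generate_phenotype(
        duos, panel, residual_sd=residual_sd, contamination=contamination, seed=ss[1]
    )


# ---------------------------------------------------------------------------
# TSV round-trips

def write_panel(panel: SnpPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> SnpPanel:
    return SnpPanel.from_frame(pd.read_csv(path, sep="\t"))


def write_cohort(
    cohort: DuoCohort, prefix: str | Path, panel: SnpPanel | None = None
) -> list[Path]:
    """Write fetal/maternal dosage TSVs (rows=individuals) plus phenotypes.

    Dosage columns are named by the panel's variant IDs when a panel is given.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    ids = cohort.phenotypes["individual_id"]
    if panel is not None:
        columns = list(panel.variant_id)
    else:
        columns = [f"snp{j + 1}" for j in range(cohort.n_snps)]
    for name, g in (("fetal", cohort.g_fetal), ("maternal", cohort.g_maternal)):
        if g is None:
            continue
        df = pd.DataFrame(g, columns=columns)
        df.insert(0, "individual_id", ids)
        p = prefix.with_name(prefix.name + f".{name}_dosages.tsv")
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    p = prefix.with_name(prefix.name + ".phenotypes.tsv")
    cohort.phenotypes.to_csv(p, sep="\t", index=False)
    written.append(p)
    if panel is not None:
        # allele sidecar so downstream ingestion can harmonise orientation
        info = pd.DataFrame(
            {
                "variant_id": panel.variant_id,
                "effect_allele": panel.effect_allele,
                "other_allele": panel.other_allele,
            }
        )
        p = prefix.with_name(prefix.name + ".variant_info.tsv")
        info.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def read_cohort(prefix: str | Path, cohort_id: str = "SIM") -> DuoCohort:
    prefix = Path(prefix)
    phen = pd.read_csv(prefix.with_name(prefix.name + ".phenotypes.tsv"), sep="\t")
    fet = pd.read_csv(prefix.with_name(prefix.name + ".fetal_dosages.tsv"), sep="\t")
    g_fet = fet.drop(columns="individual_id").to_numpy(dtype=float)
    mat_path = prefix.with_name(prefix.name + ".maternal_dosages.tsv")
    g_mat = None
    if mat_path.exists():
        g_mat = (
            pd.read_csv(mat_path, sep="\t")
            .drop(columns="individual_id")
            .to_numpy(dtype=float)
        )
    if "cohort_id" in phen.columns and len(phen):
        cohort_id = str(phen["cohort_id"].iloc[0])
    return DuoCohort(cohort_id=cohort_id, g_fetal=g_fet, g_maternal=g_mat, phenotypes=phen)
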