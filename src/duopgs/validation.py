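"""Simulation studies that characterise the deviation test.

Two canned experiments used by both the test suite and the reproduction
script:

* :func:`calibration_study` — type-I error of the lowest-bin empirical p
  under the additive polygenic model the null assumes (fetal effects only;
  a correlated unscored-parent contribution is itself a model violation and
  genuinely shifts tail bin means, so it is not a calibration condition).
* :func:`power_study` — detection of an injected environmental deficit in
  the smallest babies, across contamination fractions.  Contamination sets
  are nested within a shared base cohort per replicate (common random
  numbers), which sharpens the monotone dose-response comparison without
  changing any arm's marginal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deviation import (
    BinSpec,
    conditional_betas,
    empirical_p,
    observed_bin_means,
    simulate_null,
)
from .phenotype import ZScoreTable
from .simulate import (
    SnpPanel,
    effect_sd_for_variance,
    generate_duos,
    generate_panel,
)

__all__ = ["calibration_study", "power_study", "PowerArm"]

# deviation studies run on a 50-SNP panel explaining 7% of phenotype
# variance, a desk-scale stand-in for a genome-wide significant panel
STUDY_N_SNPS = 50
STUDY_GS_VARIANCE = 0.07


def _study_panel(rng_seed) -> SnpPanel:
    panel = generate_panel(
        STUDY_N_SNPS,
        freq_range=(0.05, 0.95),
        effect_sd=effect_sd_for_variance(STUDY_GS_VARIANCE, STUDY_N_SNPS),
        maternal_fetal_corr=0.0,
        seed=rng_seed,
    )
    # fetal-effects-only generative model: the phenotype is exactly
    # "fetal score + independent noise", the null the test simulates
    panel.true_beta_maternal = np.zeros(panel.n_snps)
    panel.w_maternal = panel.w_fetal.copy()
    return panel


def _one_dataset(
    panel: SnpPanel,
    n: int,
    ss: np.random.SeedSequence,
    shift_sd: float = 0.0,
    fractions: tuple[float, ...] = (0.0,),
):
    """Base duo dataset plus nested contaminated phenotype versions.

    Returns (duos, dict fraction -> bw_z array).  The contaminated set for a
    smaller fraction is a subset of that for a larger one.
    """
    child_seed, noise_seed, perm_seed = ss.spawn(3)
    duos = generate_duos(panel, n, seed=child_seed)
    rng = np.random.default_rng(noise_seed)
    f = panel.freq
    var_g = float(np.sum(2 * f * (1 - f) * panel.true_beta_fetal**2))
    base = (duos.g_fetal - 2 * f) @ panel.true_beta_fetal + rng.normal(
        0.0, np.sqrt(1 - var_g), size=n
    )
    perm = np.random.default_rng(perm_seed).permutation(n)
    versions = {}
    for frac in fractions:
        z = base.copy()
        k = int(round(frac * n))
        if k:
            z[perm[:k]] -= shift_sd
        versions[frac] = z
    return duos, versions


def _lowest_bin_result(
    duos,
    bw_z: np.ndarray,
    bins: BinSpec,
    n_sims: int,
    null_seed,
):
    z = ZScoreTable(
        individual_id=duos.phenotypes["individual_id"].to_numpy(dtype=object),
        bw_z=bw_z,
        method="within_cohort_residual",
    )
    cb = conditional_betas(duos, z, member="fetal")
    raw = (duos.g_fetal - 2 * cb.freq_obs) @ cb.beta_cond
    observed = observed_bin_means(raw, z, bins)
    null = simulate_null(cb, duos.n, n_sims=n_sims, bins=bins, seed=null_seed)
    return empirical_p(observed, null, bins, n=duos.n)[0]


def calibration_study(
    n_datasets: int = 200,
    n: int = 2000,
    n_sims: int = 500,
    bin_width: float = 10.0,
    seed: int | None = None,
) -> dict:
    """Lowest-bin rejection rate at nominal 0.05 under the additive model."""
    root = np.random.SeedSequence(seed)
    panel_seed, *dataset_seeds = root.spawn(n_datasets + 1)
    panel = _study_panel(panel_seed)
    bins = BinSpec(bin_width, "lower")
    pvals = np.empty(n_datasets)
    for r, ds in enumerate(dataset_seeds):
        data_ss, null_ss = ds.spawn(2)
        duos, versions = _one_dataset(panel, n, data_ss)
        res = _lowest_bin_result(duos, versions[0.0], bins, n_sims, null_ss)
        pvals[r] = res.p_emp
    rate = float(np.mean(pvals <= 0.05))
    return {
        "p_values": pvals,
        "rejection_rate": rate,
        "n_datasets": n_datasets,
        "se_binomial": float(np.sqrt(0.05 * 0.95 / n_datasets)),
    }


@dataclass
class PowerArm:
    fraction: float
    detection_rate: float
    direction_rate: float  # share of replicates with observed above null mean
    n_replicates: int


def power_study(
    fractions: tuple[float, ...] = (0.01, 0.03, 0.10),
    shift_sd: float = 1.5,
    n: int = 5000,
    n_sims: int = 1000,
    n_replicates: int = 40,
    bin_width: float = 3.0,
    seed: int | None = None,
) -> list[PowerArm]:
    """Detection of an environmental deficit in the lowest phenotype bin.

    Detection = two-sided empirical p <= 0.05 in the lowest bin; direction =
    observed bin mean above the null mean (scores higher than the observed
    birth weight predicts).
    """
    root = np.random.SeedSequence(seed)
    panel_seed, *rep_seeds = root.spawn(n_replicates + 1)
    panel = _study_panel(panel_seed)
    bins = BinSpec(bin_width, "lower")
    fractions = tuple(sorted(fractions))
    detected = {f: 0 for f in fractions}
    above = {f: 0 for f in fractions}
    for ds in rep_seeds:
        data_ss, null_ss = ds.spawn(2)
        duos, versions = _one_dataset(
            panel, n, data_ss, shift_sd=shift_sd, fractions=fractions
        )
        for frac in fractions:
            res = _lowest_bin_result(duos, versions[frac], bins, n_sims, null_ss)
            detected[frac] += res.p_emp <= 0.05
            above[frac] += res.observed_mean > res.null_mean
    return [
        PowerArm(
            fraction=frac,
            detection_rate=detected[frac] / n_replicates,
            direction_rate=above[frac] / n_replicates,
            n_replicates=n_replicates,
        )
        for frac in fractions
    ]
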