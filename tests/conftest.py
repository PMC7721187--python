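import numpy as np
import pytest

import duopgs


@pytest.fixture(scope="session")
def panel():
    """Mid-sized panel with correlated maternal/fetal effects."""
    return duopgs.generate_panel(
        n_snps=60,
        freq_range=(0.1, 0.9),
        effect_sd=duopgs.effect_sd_for_variance(0.07, 60, (0.1, 0.9)),
        maternal_fetal_corr=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(panel):
    """Simulated duo cohort with phenotypes, no contamination."""
    return duopgs.generate_cohort(panel, n=4000, seed=11, cohort_id="COH1")


@pytest.fixture(scope="session")
def zscores(cohort):
    return duopgs.zscore_within_cohort(cohort.phenotypes)


@pytest.fixture(scope="session")
def term_cohort(cohort, zscores):
    """Cohort restricted to the term individuals the z-scores cover."""
    keep = np.isin(
        cohort.phenotypes["individual_id"].to_numpy(dtype=object),
        zscores.individual_id,
    )
    return duopgs.DuoCohort(
        cohort_id=cohort.cohort_id,
        g_fetal=cohort.g_fetal[keep],
        g_maternal=cohort.g_maternal[keep],
        phenotypes=cohort.phenotypes[keep].reset_index(drop=True),
    )
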