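import numpy as np
import pandas as pd
import pytest

from lncemt.synthetic import SyntheticConfig, generate_cohort, generate_conservation


@pytest.fixture(scope="session")
def cohort_truth():
    """Default synthetic cohort (planted regulators, realistic noise)."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def quiet_cohort_truth():
    """Near-noiseless cohort for separation / exact-recovery checks.

    Both the residual noise and the small intrinsic per-gene subtype shifts
    are switched off, so planted regulation is the only subtype-linked
    signal.
    """
    return generate_cohort(
        SyntheticConfig(noise_sd=0.01, gene_subtype_shift_sd=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def quiet_tracks(quiet_cohort_truth):
    cohort, truth = quiet_cohort_truth
    return generate_conservation(cohort.lncrnas, truth.regulators, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_subtype(n_epi, n_mes, samples=None):
    if samples is None:
        samples = [f"s{i}" for i in range(n_epi + n_mes)]
    return pd.Series(
        ["epithelial"] * n_epi + ["mesenchymal"] * n_mes, index=samples, name="subtype"
    )
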