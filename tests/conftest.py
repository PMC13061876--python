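import numpy as np
import pytest

import ifmicrostate as ifm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 5 participants, 20 s each (10 s usable after trims), high SNR.

    Returns (spec, list of (recording, truth)).
    """
    spec = ifm.default_cohort_spec(seed=42, n_per_group=(8, 5),
                                   duration_s=20.0, noise_sd=0.05)
    return spec, ifm.make_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_series(small_cohort):
    """Preprocessed + IF-extracted + z-scored series with aligned truth."""
    spec, cohort = small_cohort
    n_trim = int(5.0 * spec.fs_hz)
    series, truths = [], []
    for rec, truth in cohort:
        pre = ifm.trim_edges(ifm.bandpass(rec), 5.0)
        series.append(ifm.spatial_normalize(ifm.extract_if(pre)))
        truths.append(truth.state_sequence[n_trim:-n_trim])
    return spec, series, truths
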