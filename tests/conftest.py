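import numpy as np
import pytest

from gatefret import synthetic_data as sd
from gatefret.fret_histograms import fit_staged_mixture, histograms_from_samples

#: component parameters of the three lateral-gate states (mean, FWHM)
STATE_MEANS = (0.76, 0.59, 0.45)
STATE_WIDTHS = (0.24, 0.16, 0.31)


@pytest.fixture(scope="session")
def study_histograms():
    """Six-condition replicate histogram set at the study parameters."""
    samples = sd.sample_condition_set(seed=7)
    return histograms_from_samples(samples)


@pytest.fixture(scope="session")
def staged_fit(study_histograms):
    """Staged three-Gaussian global fit of the session study set."""
    return fit_staged_mixture(study_histograms, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
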