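import numpy as np
import pytest

from semgspec import synthetic


@pytest.fixture(scope="session")
def default_templates():
    return synthetic.default_templates()


@pytest.fixture(scope="session")
def noisefree_spectra():
    """Noise-free two-component spectra matrix: exactly rank 2.

    The generator's epoch-to-epoch weight jitter stays on (it lives inside
    the ground-truth W, so the matrix is still an exact bilinear product);
    only the additive bin noise is off. The jitter spreads rows toward the
    component axes, which is what makes the factorization identifiable.
    """
    truth = synthetic.make_ground_truth(seed=11, noise_sd=0.0)
    return synthetic.synthesize_spectra(truth)


@pytest.fixture(scope="session")
def default_spectra():
    """One default-condition (jittered, noisy) spectra matrix."""
    truth = synthetic.make_ground_truth(seed=7)
    return synthetic.synthesize_spectra(truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
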