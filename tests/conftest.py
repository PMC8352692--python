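import numpy as np
import pytest

from cc_extract import PhantomSpec, generate_phantom
from cc_extract.synthetic_phantom import vary


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default phantom rendered without noise: four exact gray levels."""
    spec = vary(PhantomSpec(), noise_sigma=0.0)
    img, cc_gt, brain_gt = generate_phantom(spec)
    return img, cc_gt, brain_gt, spec


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with moderate acquisition noise."""
    spec = PhantomSpec(seed=7, noise_sigma=3.0)
    img, cc_gt, brain_gt = generate_phantom(spec)
    return img, cc_gt, brain_gt, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
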