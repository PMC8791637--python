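import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def droplet_field():
    """A shared 3-channel droplet field with blur, offset and noise."""
    from phaseq import synthetic
    from phaseq.synthetic import DropletSpec

    rng = np.random.default_rng(77)
    bulk = {"647": 100.0, "488": 120.0, "546": 80.0}
    true_pc = {"647": 3.0, "488": 1.5, "546": 1.0}
    specs = []
    for i in range(4):
        for j in range(4):
            d = rng.uniform(13, 45)
            specs.append(
                DropletSpec(
                    (70 + 120 * i + rng.uniform(-6, 6), 70 + 120 * j + rng.uniform(-6, 6)),
                    d,
                    {ch: bulk[ch] * true_pc[ch] for ch in bulk},
                )
            )
    images, truth = synthetic.make_droplet_image(
        specs, bulk, psf_fwhm=4.0, background_offset=40.0, noise_sd=2.0, seed=99,
        shape=(520, 520),
    )
    return images, truth, true_pc
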