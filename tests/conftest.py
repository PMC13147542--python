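import numpy as np
import pytest

from mlpquant import imaging, synth


@pytest.fixture(scope="session")
def filled_plate():
    """A plate image with strong growth at every position (layout reference)."""
    spec = synth.PlateSpec(
        densities=np.full((8, 12), 0.8),
        ratios=np.ones((8, 12)),
        noise_sd=1.0,
        seed=0,
    )
    image, _, _ = synth.render_plate_pair(spec)
    return spec, image


@pytest.fixture(scope="session")
def reference_layout(filled_plate):
    _, image = filled_plate
    return imaging.build_reference_layout(image)


@pytest.fixture(scope="session")
def toy_genome_fixture():
    return synth.toy_genome(seed=1)
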