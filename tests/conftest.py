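import pytest

from histoquant.detection import DetectionParams
from histoquant.stains import hdab_profile
from histoquant.synthetic import CoreSpec, gen_core


@pytest.fixture(scope="session")
def hdab():
    return hdab_profile()


@pytest.fixture(scope="session")
def params():
    return DetectionParams()


@pytest.fixture(scope="session")
def ihc_core():
    """One rendered IHC core (100 cells, 30% DAB-positive, noise sd 3) with
    its truth table; scaled to a 400 µm core at 0.5 µm/px so the whole
    suite stays fast."""
    spec = CoreSpec(seed=1, pixel_size_um=0.5, diameter_um=400.0, n_cells=100, noise_sd=3.0)
    image, truth = gen_core(spec)
    return image, truth, spec
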