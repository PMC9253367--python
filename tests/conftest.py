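import numpy as np
import pytest

from loopkin.fitting import build_template_tube
from loopkin.phantoms import PhantomSpec


@pytest.fixture(scope="session")
def template():
    """Default 56-node / 24-element straight tube template."""
    return build_template_tube()


@pytest.fixture(scope="session")
def desk_spec():
    """Reduced-scale phantom spec usable for voxel-level tests."""
    return PhantomSpec.desk(seed=11)


@pytest.fixture(scope="session")
def full_spec():
    """Full-scale (study-condition) phantom spec."""
    return PhantomSpec(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
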