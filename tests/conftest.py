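import numpy as np
import pytest

from vitunet3d.data import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom32():
    """One 32^3 synthetic case with all four label classes present."""
    return generate_phantom(PhantomSpec(extents=(32, 32, 32),
                                        tumor_fraction=0.05, seed=1))


@pytest.fixture(scope="session")
def phantom_suite():
    from vitunet3d.data import generate_phantom_suite
    return generate_phantom_suite(8, seed=7,
                                  base=PhantomSpec(extents=(24, 24, 24),
                                                   tumor_fraction=0.06))
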