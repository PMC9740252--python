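import numpy as np
import pytest

from epimech import synthetic


@pytest.fixture(scope="session")
def monolayer():
    """Noise-free 25-cell monolayer with J=200, C=100 and its truth."""
    return synthetic.make_monolayer(n_cells=25, shape=(400, 400), J=200.0,
                                    C=100.0, B=0.0, noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def tfm_dipole():
    """Balanced contractile dipole bead-image pair, noise-free."""
    spots = synthetic.dipole_spots((48.0, 48.0), 24.0, 400.0, 6.0)
    return synthetic.make_tfm_pair(spots, domain_um=96.0, h=2.6,
                                   bead_density=1.0, loc_noise_px=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
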