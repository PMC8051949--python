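import numpy as np
import pytest

from nuctension import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_bt_model():
    """Bleed-through model calibrated once from simulated control fields."""
    from nuctension import fret

    donor_cfg = syn.FretSimConfig(
        n_nuclei=10, image_shape=(400, 400), mode="donor_only", seed=101
    )
    acceptor_cfg = syn.FretSimConfig(
        n_nuclei=10, image_shape=(400, 400), mode="acceptor_only", seed=102
    )
    d, _ = syn.simulate_fret_image_set(donor_cfg)
    a, _ = syn.simulate_fret_image_set(acceptor_cfg)
    return fret.estimate_bleedthrough([d], [a])
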