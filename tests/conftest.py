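import numpy as np
import pytest

from evcq import simgen


@pytest.fixture
def noiseless_config():
    """Factory for small deterministic (no shot/read noise) field configs."""

    def make(seed=0, n_frames=1, **overrides):
        kwargs = dict(
            width_px=220,
            height_px=220,
            background_adu=20.0,
            read_noise_adu=0.0,
            shot_noise=False,
            n_frames=n_frames,
            frame_interval_s=1.0,
            seed=seed,
        )
        kwargs.update(overrides)
        return simgen.SimImageConfig(**kwargs)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
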