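import numpy as np
import pytest

from alphaloop import (add_alpha, alpha_rms_for_snr, generate_background)
from alphaloop.montage import OCCIPITOPARIETAL


@pytest.fixture(scope="session")
def op_alpha_recording():
    """60 s occipitoparietal recording with a constant 10.4 Hz alpha peak."""
    rng = np.random.default_rng(1234)
    rec = generate_background(60.0, channel_names=OCCIPITOPARIETAL, seed=rng)
    return add_alpha(rec, np.array([10.4]),
                     alpha_rms_for_snr(60.0) * np.ones(6), seed=rng)


@pytest.fixture(scope="session")
def op_background_recording():
    """60 s occipitoparietal recording with no alpha oscillation at all."""
    return generate_background(60.0, channel_names=OCCIPITOPARIETAL, seed=77)
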