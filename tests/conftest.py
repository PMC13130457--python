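import numpy as np
import pytest

from fiberquant import VolumeImage, make_fiber_frame


@pytest.fixture(scope="session")
def small_fiber_fixture():
    """A modest oriented-rod frame shared by orientation tests (seeded)."""
    frame, truth = make_fiber_frame(
        120, (0.2, 0.3, 0.5), fiber_angle_deg=30.0, noise_sd=5.0, seed=42
    )
    return frame, truth


def frame_to_stack(frame, channel="tomm20"):
    """Wrap a PlaneImage into a single-plane VolumeImage stack."""
    return VolumeImage(
        frame.pixels[np.newaxis, np.newaxis], (1.0, *frame.spacing), (channel,)
    )
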