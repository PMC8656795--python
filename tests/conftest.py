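import numpy as np
import pytest

from ssopkit import (
    OpticalProperties,
    build_lut,
    load_extinction_table,
    make_phantom,
    render_frames,
    render_reference,
)
from ssopkit.demodulation import THREE_PHASES

REF_OP = OpticalProperties(mu_a=0.01, mu_s_prime=1.0, n=1.4)


@pytest.fixture(scope="session")
def default_lut():
    return build_lut()


@pytest.fixture(scope="session")
def extinction():
    return load_extinction_table()


@pytest.fixture(scope="session")
def four_roi_scene():
    return make_phantom("four_roi")


@pytest.fixture(scope="session")
def four_roi_sfdi(four_roi_scene):
    """Noiseless three-phase acquisition of the four-ROI scene + reference."""
    acq = render_frames(four_roi_scene, (0.2,), THREE_PHASES)
    ref = render_reference(REF_OP, shape=four_roi_scene.shape)
    return acq, ref


@pytest.fixture(scope="session")
def four_roi_ssop(four_roi_scene):
    """Noiseless single-snapshot acquisition of the same scene + reference."""
    acq = render_frames(four_roi_scene, (0.2,), (0.0,))
    ref = render_reference(REF_OP, shape=four_roi_scene.shape, phases=(0.0,))
    return acq, ref


def interior_mask(shape, margin, discontinuity_map=None):
    """Pixels at least `margin` from the borders along the modulation axis,
    and away from property discontinuities (SSOP ringing zones)."""
    from scipy.ndimage import binary_dilation

    m = np.zeros(shape, dtype=bool)
    m[:, margin:-margin] = True
    if discontinuity_map is not None:
        disc = np.zeros(shape, dtype=bool)
        disc[:, 1:] = np.abs(np.diff(discontinuity_map, axis=1)) > 0
        m &= ~binary_dilation(disc, np.ones((1, 2 * margin + 1), dtype=bool))
    return m
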