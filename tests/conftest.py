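import numpy as np
import pytest

from laryngotopo import SyntheticSceneConfig, generate_recording, run_on_recording


def small_scene_config(**kw):
    """A fast 64x64, 96-frame scene (25 Hz bins, F0 150 = 6 bins)."""
    defaults = dict(
        shape=(64, 64),
        n_frames=96,
        fps=2400.0,
        f0=150.0,
        fold_halfwidth=10,
        fold_halfheight=22,
    )
    defaults.update(kw)
    return SyntheticSceneConfig(**defaults)


@pytest.fixture(scope="session")
def quarter_scene():
    """Desk-scale noiseless scene: affected (left) fold vibrating over a
    quarter of its area, non-affected fold fully vibrating."""
    cfg = SyntheticSceneConfig(vib_frac_left=0.25, vib_frac_right=1.0)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def quarter_result(quarter_scene):
    rec, gt = quarter_scene
    return run_on_recording(rec, gt.landmarks()), gt


@pytest.fixture(scope="session")
def small_scene():
    cfg = small_scene_config(vib_frac_left=0.5, vib_frac_right=1.0)
    return generate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def textured_frame(rng, shape=(48, 48), margin=16):
    """A frame with rich interior structure and a dark margin, so integer
    translations are unambiguous within the margin."""
    h, w = shape
    img = np.zeros((h, w), dtype=np.uint8)
    interior = rng.integers(20, 235, size=(h - 2 * margin, w - 2 * margin))
    img[margin : h - margin, margin : w - margin] = interior
    return img
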