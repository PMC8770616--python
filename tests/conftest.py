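import numpy as np
import pytest
from hypothesis import settings
from skimage.draw import disk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tdluquant import classes as C
from tdluquant.annotations import LabelMap


def make_map(shape=(64, 64), fill=C.EXTRALOBULAR_STROMA):
    return np.full(shape, fill, dtype=np.uint8)


def draw_disc(codes, center, radius, code):
    rr, cc = disk(center, radius, shape=codes.shape)
    codes[rr, cc] = code
    return codes


@pytest.fixture
def small_scene():
    """One deterministic level-5 scene (few acini, fast to render)."""
    from tdluquant.synthetic import SceneParams, generate_scene

    params = SceneParams(canvas_size=512, involution_level=5, n_acini=4, seed=1)
    rgb, truth = generate_scene(params)
    return params, rgb, truth


@pytest.fixture
def ring_map():
    """An epithelial ring (outer r=30, lumen r=12) in intralobular stroma."""
    codes = make_map((128, 128), C.INTRALOBULAR_STROMA)
    draw_disc(codes, (64, 64), 30, C.EPITHELIUM)
    draw_disc(codes, (64, 64), 12, C.LUMEN)
    return LabelMap(codes)
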