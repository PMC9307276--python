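import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def world():
    from pcm_selforg.config import WorldParams

    return WorldParams()


@pytest.fixture
def fiber():
    from pcm_selforg.config import FiberParams

    return FiberParams()


def straight_filament(n=6, seg=0.5, origin=(0.0, 0.0), direction=(1.0, 0.0)):
    from pcm_selforg.filaments import Filament

    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.hypot(*d)
    verts = o + seg * np.arange(n)[:, None] * d
    return Filament(vertices=verts, rest_segment_length=seg, last_rest=seg)
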