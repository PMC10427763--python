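import numpy as np
import pytest

from twitchkit import synthetic as syn
from twitchkit import piv


@pytest.fixture(scope="session")
def speckle_frame():
    """Static textured frame with enough structure for window correlation."""
    rng = np.random.default_rng(42)
    return syn.speckle((192, 192), rng, grain=3.0) * 100.0


@pytest.fixture(scope="session")
def sine_movie():
    """Standard study-condition movie: 5 Hz sine, 1 µm amplitude, 2 s @ 20 ms."""
    spec = syn.WaveformSpec(
        kind="sine", frequency=5.0, amplitude=1.0, duration=2.0, sample_interval=0.02
    )
    scene = syn.make_tube_scene(noise_sd=2.0)
    stack, truth = syn.generate_movie(spec, scene, seed=7)
    return spec, scene, stack, truth


@pytest.fixture(scope="session")
def sine_movie_trace(sine_movie):
    """PIV-tracked trace of the central nucleus of the standard movie."""
    spec, scene, stack, truth = sine_movie
    fields = piv.movie_to_fields(stack)
    nuc = scene.nuclei[1]
    start = (nuc.center[0] / scene.pixel_size, nuc.center[1] / scene.pixel_size)
    trace = piv.track_point(fields, start, stack.pixel_size, stack.frame_interval)
    return spec, scene, trace, truth[1]
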