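import numpy as np
import pytest

from mechanoquant import synthetic_data as synth


@pytest.fixture(scope="session")
def small_scene():
    """4x4 noise-free pillar scene with linear drift, 12 frames."""
    return synth.make_pillar_scene(n_rows=4, n_cols=4, n_frames=12,
                                   snr=np.inf,
                                   drift_per_frame_px=(0.10, -0.05), seed=2)


@pytest.fixture(scope="session")
def static_scene():
    """4x4 noise-free scene with no motion at all."""
    return synth.make_pillar_scene(n_rows=4, n_cols=4, n_frames=6,
                                   snr=np.inf, drift_per_frame_px=(0.0, 0.0),
                                   max_displacement_px=0.0, seed=3)


@pytest.fixture(scope="session")
def blob_scene12():
    return synth.make_blob_scene(n_blobs=12, seed=5)
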