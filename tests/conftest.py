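import numpy as np
import pandas as pd
import pytest

from fcdtools import synthetic, transcriptomics
from fcdtools.datatypes import CONFOUND_COLUMNS, MOTION_COLUMNS, BoldSession


@pytest.fixture(scope="session")
def small_parcellation():
    return synthetic.make_parcellation((10, 10, 10), 20, seed=7)


@pytest.fixture(scope="session")
def brain_scale_parcellation():
    """200 cortical regions spanning ~100x100x70 mm (5 mm voxels)."""
    return synthetic.make_parcellation((20, 20, 14), 200, seed=3, voxel_size_mm=5.0)


@pytest.fixture(scope="session")
def cortical_distances(brain_scale_parcellation):
    return transcriptomics.region_distances(brain_scale_parcellation, "cortical")


@pytest.fixture(scope="session")
def hub_session(small_parcellation):
    return synthetic.make_bold_session(
        small_parcellation,
        hub_regions=(1, 2),
        hub_strength=0.9,
        ar_coef=0.3,
        n_frames=240,
        seed=1,
    )


def make_session_from_array(data, tr_s=2.5, mask=None, motion=None):
    """Wrap a raw 4-D array as a BoldSession with neutral confounds."""
    data = np.asarray(data, dtype=float)
    t = data.shape[3]
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    if motion is None:
        motion = pd.DataFrame(np.zeros((t, 6)), columns=MOTION_COLUMNS)
    confounds = pd.DataFrame(np.zeros((t, 3)), columns=CONFOUND_COLUMNS)
    return BoldSession(data=data, tr_s=tr_s, mask=mask, confounds=confounds, motion=motion)
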