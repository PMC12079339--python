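import numpy as np
import pandas as pd
import pytest

from sps.stack import MaskedImageStack
from sps.synth import SyntheticTruth, generate_contrast_stack


@pytest.fixture(scope="session")
def small_truth() -> SyntheticTruth:
    """Small cohort on a 12^3 grid for fast decoding tests."""
    return SyntheticTruth(grid_shape=(12, 12, 12), subject_count=12, seed=3)


@pytest.fixture(scope="session")
def small_stack(small_truth) -> MaskedImageStack:
    return generate_contrast_stack(small_truth)


@pytest.fixture(scope="session")
def hi_snr_truth() -> SyntheticTruth:
    """High-SNR cohort: near-noiseless pattern expression."""
    return SyntheticTruth(grid_shape=(12, 12, 12), subject_count=12, seed=4,
                          noise_sd=0.02)


@pytest.fixture(scope="session")
def hi_snr_stack(hi_snr_truth) -> MaskedImageStack:
    return generate_contrast_stack(hi_snr_truth)


def toy_stack(data, n_conds=2, conds=None, mask_shape=(10, 10, 10)):
    """Wrap a 2-D array as a stack: rows cycle through conditions within
    subjects."""
    data = np.asarray(data, dtype=float)
    n_obs, v = data.shape
    conds = conds or [f"c{i}" for i in range(n_conds)]
    mask = np.zeros(mask_shape, bool)
    mask.ravel()[:v] = True
    meta = pd.DataFrame(
        {
            "subject": [f"s{i // len(conds):02d}" for i in range(n_obs)],
            "condition": [conds[i % len(conds)] for i in range(n_obs)],
        }
    )
    return MaskedImageStack(data=data, mask=mask, affine=np.eye(4), obs_meta=meta)
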