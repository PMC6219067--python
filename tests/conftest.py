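import numpy as np
import pytest

from fastla import PhantomConfig, TrackerConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default-condition phantom (normal-control deformation), seed 0."""
    return generate_phantom(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def subpixel_tracker():
    return TrackerConfig(subpixel=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_ncc(template: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Independent per-offset Pearson correlation (double loop)."""
    th, tw = template.shape
    out = np.empty((region.shape[0] - th + 1, region.shape[1] - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            window = region[i : i + th, j : j + tw]
            out[i, j] = np.corrcoef(template.ravel(), window.ravel())[0, 1]
    return out
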