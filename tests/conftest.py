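import numpy as np
import pytest

from seiznet.core import Segment


def make_segment(
    samples: np.ndarray,
    fs: float = 100.0,
    condition: str = "interictal",
    onset_time: float | None = None,
) -> Segment:
    """Wrap a plain sample matrix in a Segment with default metadata."""
    n = samples.shape[0]
    half = n // 2
    return Segment(
        samples=samples,
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(n)],
        hemispheres=["L"] * half + ["R"] * (n - half),
        condition=condition,
        onset_time=samples.shape[1] / fs / 2 if onset_time is None else onset_time,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Unit-weight 3-clique."""
    return np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
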