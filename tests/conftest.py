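import numpy as np
import pytest

from crpcoord import SegmentSeries


def make_series(n=600, cycles=10.0, amplitude=30.0, offset=10.0, delay=0.0,
                fs=60.0, segment_label="shank", side="right"):
    """Sampled cosine segment angle: offset + amplitude·cos(2πf(t − delay))."""
    t = np.arange(n) / fs
    f = cycles / (n / fs)
    angle = offset + amplitude * np.cos(2 * np.pi * f * (t - delay))
    return SegmentSeries(time=t, angle=angle, segment_label=segment_label, side=side)


@pytest.fixture
def sinusoid_pair():
    """Identical shank/thigh cosine series (fully in-phase)."""
    return (make_series(segment_label="shank"),
            make_series(segment_label="thigh"))


def interior_slice(n, margin=0.1):
    k = int(np.floor(n * margin))
    return slice(k, n - k)
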