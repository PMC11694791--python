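import numpy as np
import pytest

from infrakit import ActivityRecord


def tone_record(periods_hours, amplitudes, days=28.0, bin_minutes=5.0,
                noise_sd=0.0, offset=None, seed=0):
    """Noisy sum-of-sinusoids count record (deterministic for a seed)."""
    rng = np.random.default_rng(seed)
    n = int(round(days * 24 * 60 / bin_minutes))
    t = (np.arange(n) + 0.5) * bin_minutes / 60.0
    y = np.zeros(n)
    for p, a in zip(periods_hours, amplitudes):
        y += a * np.sin(2 * np.pi * t / p)
    if noise_sd > 0:
        y += rng.normal(0, noise_sd, n)
    if offset is None:
        offset = -y.min() if y.size else 0.0
    return ActivityRecord(counts=y + offset, bin_width=bin_minutes)


@pytest.fixture
def zigzag_corners():
    """Right-angle staircase with 2-cm legs: the spatial-d hand fixture."""
    pts = [(0.0, 0.0)]
    for i in range(4):
        pts.append((2 * i + 2, 2 * i))
        pts.append((2 * i + 2, 2 * i + 2))
    return np.array(pts)[:9]
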