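import numpy as np
import pytest

from circalarva.bouts import segment_bouts
from circalarva.model import LightSchedule


@pytest.fixture
def toy_bouts():
    """600-s track: A 100 s (50 mm), I 30 s, A 70 s (21 mm), I 120 s, A 280 s (84 mm)."""
    active = np.r_[
        np.ones(100), np.zeros(30), np.ones(70), np.zeros(120), np.ones(280)
    ].astype(bool)
    dist = np.zeros(600)
    dist[:100] = 0.5  # 50 mm
    dist[130:200] = 0.3  # 21 mm
    dist[320:] = 0.3  # 84 mm
    return segment_bouts(active, 1.0, dist, "toy")


@pytest.fixture
def pulse12():
    return LightSchedule.pulse(12.0)


def brute_force_rle(seq):
    """Independent run-length encoder: linear scan, no numpy tricks."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((bool(seq[start]), start, i - start))
            start = i
    return runs
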