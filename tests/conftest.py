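import numpy as np
import pytest

from cmrpop.encounter_data import CaptureHistorySet, EncounterHistory


def make_set(patterns, occasions=None, group="g"):
    """Build a CaptureHistorySet from '101'-style strings."""
    t = len(patterns[0])
    occ = tuple(occasions) if occasions else tuple(range(2000, 2000 + t))
    hists = tuple(
        EncounterHistory(f"i{k}", group, tuple(int(c) for c in pat))
        for k, pat in enumerate(patterns)
    )
    return CaptureHistorySet(occ, hists)


def random_set(rng, t, n, group="g"):
    """Random valid history set (every bird detected at least once)."""
    hists = []
    for i in range(n):
        d = rng.integers(0, 2, t)
        if d.sum() == 0:
            d[rng.integers(t)] = 1
        hists.append(
            EncounterHistory(f"h{i}", group, tuple(int(x) for x in d))
        )
    return CaptureHistorySet(tuple(range(2000, 2000 + t)), tuple(hists))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def three_occasion_set():
    return make_set(["101", "110", "100"])
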