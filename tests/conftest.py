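import numpy as np
import pytest

from sleepv2g.restriction import DPNII, FragmentMap


@pytest.fixture
def rng():
    return np.random.default_rng(20230106)


@pytest.fixture
def random_digest(rng):
    """A random two-chromosome DpnII digest for map-level properties."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        f"chr{i}": rng.choice(bases, size=30_000).tobytes().decode("ascii")
        for i in (1, 2)
    }
    return seqs, FragmentMap.from_sequences(seqs, DPNII)


def bruteforce_sleep_minutes(counts, threshold=5):
    """Independent run-length oracle: scan zero runs with itertools.groupby."""
    import itertools

    state = []
    for is_zero, grp in itertools.groupby(counts, key=lambda c: c == 0):
        run = list(grp)
        state.extend([is_zero and len(run) >= threshold] * len(run))
    return state
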