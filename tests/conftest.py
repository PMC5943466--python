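import numpy as np
import pytest
from hypothesis import settings

from neutrokit import generate_reference_cohort

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_cohort():
    """Cohort reconstructing the published Cycle-1 DSN distribution."""
    return generate_reference_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def dsn_bruteforce(observations):
    """Independent DSN oracle: enumerate all (grade-4 day, recovery day)
    pairs and take the shortest interval anchored at the earliest onset."""
    severe = [d for d, a in observations if a < 0.5]
    if not severe:
        return 0, False
    onset = min(severe)
    pairs = [
        (d0, r)
        for d0, a0 in observations
        if a0 < 0.5
        for r, ar in observations
        if r >= d0 and ar >= 2.0
    ]
    anchored = [r - d0 for d0, r in pairs if d0 == onset]
    if anchored:
        return min(anchored), False
    last = max(d for d, _ in observations)
    return last - onset + 1, True
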