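import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from blinkssa import generate_epoch, remove_eyeblink  # noqa: E402


def diag_avg_loop(a: np.ndarray) -> np.ndarray:
    """Independent brute-force anti-diagonal mean (ascending-row summation)."""
    m, k = a.shape
    out = np.empty(m + k - 1)
    for n in range(m + k - 1):
        total = 0.0
        count = 0
        for i in range(m):
            j = n - i
            if 0 <= j < k:
                total += a[i, j]
                count += 1
        out[n] = total / count
    return out


@pytest.fixture(scope="session")
def blink_case():
    """A p=1 contaminated epoch and its pipeline result (reused read-only)."""
    epoch = generate_epoch(p=1.0, seed=42)
    return epoch, remove_eyeblink(epoch.contaminated)


@pytest.fixture(scope="session")
def clean_case():
    """A blink-free epoch and its pipeline result."""
    epoch = generate_epoch(p=1.0, seed=7, n_blinks=0)
    return epoch, remove_eyeblink(epoch.contaminated)
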