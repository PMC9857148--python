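import numpy as np
import pytest

from gmaes import HRSeries, compute_section_features

# Hand-computed worked example (12 sections of 10 s):
# MovAvHR[6] = mean(150,152,150,152,150,152) = 151.0
# dHR[6] = 160 - 151 = 9.0, %dHR[6] = 16000/151 = 105.9603
# dHR positive at sections 6,7,8; negative at 9, 10 (and 11)
TOY_VALUES = [150, 152, 150, 152, 150, 152, 160, 162, 161, 150, 148, 150]


@pytest.fixture
def toy_series():
    return HRSeries(np.array(TOY_VALUES, dtype=float))


@pytest.fixture
def toy_features(toy_series):
    return compute_section_features(toy_series, 6)


def random_hr_values(rng, n):
    """A mixed-regime random HR series: smooth drift + noise + jumps."""
    regime = rng.integers(0, 3)
    base = 150.0 + 10.0 * rng.standard_normal()
    if regime == 0:  # white noise
        vals = base + rng.normal(0, 4.0, n)
    elif regime == 1:  # random walk (lots of sign structure in dHR)
        vals = base + np.cumsum(rng.normal(0, 1.5, n))
    else:  # integer-valued plateaus with jumps (exact-zero deltas occur)
        vals = base + np.round(rng.normal(0, 5.0, n))
        vals = np.round(vals)
    return np.clip(vals, 40.0, 260.0)
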