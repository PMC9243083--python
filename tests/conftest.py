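import numpy as np
import pytest

from glutcommons import BASELINE_PARAMS, ModelParams


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    return BASELINE_PARAMS


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20220629)


def random_game(rng: np.random.Generator):
    """A random admissible (params, N) draw: k < R*a guaranteed."""
    R = 10.0 ** rng.uniform(2.5, 5.0)
    a = 10.0 ** rng.uniform(-7.0, -5.0)
    k = rng.uniform(0.01, 0.9) * R * a
    N = int(rng.integers(1, 51))
    return ModelParams(R=R, a=a, k=k), N


# Printed reference tables (N -> (transporters/cell, payoff/cell)), used as
# frozen expected values across test modules.
TABLE2_ESS = {
    1: (645_492, 3700),
    5: (1_430_884, 1558),
    10: (1_592_629, 827),
    50: (1_729_743, 172),
    100: (1_747_277, 86),
}
TABLE3_INHIBITOR = {
    1: (597_837, 1212),
    5: (1_106_639, 607),
    10: (1_217_628, 344),
    50: (1_317_444, 76),
    100: (1_330_640, 38),
}
TABLE4_STARVATION = {
    1: (298_919, 606),
    5: (553_319, 303),
    10: (608_814, 172),
    50: (658_722, 38),
    100: (665_320, 19),
}
TABLE5_GAMBIT_R = {
    1: (645_492, 75),
    5: (1_430_884, -3156),
    10: (1_592_629, -3966),
    50: (1_729_743, -4671),
    100: (1_747_277, -4762),
}
TABLE6_GAMBIT_A = {
    1: (645_492, 1206),
    5: (1_430_884, -260),
    10: (1_592_629, -793),
    50: (1_729_743, -1287),
    100: (1_747_277, -1353),
}
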