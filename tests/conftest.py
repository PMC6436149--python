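import numpy as np
import pytest

from hydrotraits.sigmoid_curves import SigmoidFit

# Published cultivar-by-treatment sigmoid parameters used as fixed inputs
# for threshold-inversion checks: (a, p50, p12, p88).
GROUP_PARAMS = {
    "golden_control": (0.95, -5.00, -2.90, -7.11),
    "golden_fertilized": (0.80, -3.65, -1.16, -6.14),
    "red_control": (1.04, -4.77, -2.85, -6.69),
    "red_fertilized": (0.92, -4.29, -2.12, -6.46),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def golden_control_fit():
    a, p50, _, _ = GROUP_PARAMS["golden_control"]
    return SigmoidFit(a=a, p50=p50)
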