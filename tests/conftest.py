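import pytest

from leafgm.constants import ConstantsRegistry
from leafgm.synth import NoiseModel, TruthSpec


@pytest.fixture(scope="session")
def registry():
    return ConstantsRegistry()


@pytest.fixture()
def noiseless_truth():
    """Default study truth (Vcmax 100, J 180, Rd 1.5, Tp 12, gm 0.3, tau 0.42)
    with every noise source switched off."""
    t = TruthSpec()
    t.noise = NoiseModel(a_frac=0.0, phi_frac=0.0, gasex_frac=0.0, delta_permil=0.0)
    return t


@pytest.fixture()
def noisy_truth():
    return TruthSpec()  # 1% multiplicative noise on A and phiPSII
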