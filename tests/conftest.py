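import numpy as np
import pytest

from findose import FiniteDoseConfig


@pytest.fixture
def default_cfg():
    """Standard in-use conditions: 10 µL on 1 cm², Vsc=0.002, Teva=1.5 h, 24 h."""
    return FiniteDoseConfig()


@pytest.fixture
def caf_stratm():
    """Caffeine / Strat-M reference parameters (Kp cm/h, K, Cv µg/mL)."""
    return dict(kp=1.23e-3, K=0.422, cv=1.00e4)


@pytest.fixture
def mp_stratm():
    """Methylparaben / Strat-M reference parameters."""
    return dict(kp=5.20e-3, K=3.08, cv=1.39e3)


@pytest.fixture
def ka_porcine():
    """Kojic acid / porcine-skin reference parameters."""
    return dict(kp=1.30e-3, K=0.108, cv=1.04e4)


@pytest.fixture
def model_grid():
    """(Kp, K, Teva) grid used for oracle-agreement and conservation checks."""
    kps = np.array([1e-5, 1e-4, 1e-3, 1e-2, 5e-2])
    ks = np.array([1e-3, 0.05, 0.5, 1.5, 5.0])
    tevas = np.array([0.0, 0.5, 1.5, 6.0, 24.0])
    return kps, ks, tevas
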