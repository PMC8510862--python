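import numpy as np
import pytest

from clotlyse.formation import run_clot_formation
from clotlyse.lysis import ClotConstants, synthetic_clot_state
from clotlyse.synthetic import SyntheticAssayConfig, generate_phenomenological


@pytest.fixture(scope="session")
def control_clot():
    """End-of-clotting state for the control condition, best-ranked rates."""
    return run_clot_formation()


@pytest.fixture(scope="session")
def fast_clot():
    """Reduced clot with a prescribed bound-plasmin load.

    Sized so a full lysis takes O(10³) fixed 0.1 s steps: fast enough for
    repeated policy comparisons, slow enough to resolve both regimes.
    """
    return synthetic_clot_state(cfr0_uM=2.0, rf0=50.0, pn_b=1e-2)


@pytest.fixture(scope="session")
def fast_constants(fast_clot):
    return ClotConstants.from_clot_state(fast_clot)


@pytest.fixture(scope="session")
def clean_assay():
    """One noise-free phenomenological channel plus its ground truth."""
    cfg = SyntheticAssayConfig(noise_sd=0.0, n_channels=1)
    traces, truth = generate_phenomenological(cfg)
    return traces[0], truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
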