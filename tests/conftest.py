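import numpy as np
import pytest

from myofib import EnsembleConfig, simulate, initial_state


@pytest.fixture(scope="session")
def steady_single_trace():
    """Four paced beats of the uncoupled myocyte at 90 % L_max, starting
    from the packaged pre-paced snapshot (already at its steady cycle)."""
    cfg = EnsembleConfig(mode="single", duration=4000.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def rest_state():
    """Packaged quiescent-cycle state of the uncoupled myocyte at 90 %."""
    return initial_state(EnsembleConfig(mode="single"))


@pytest.fixture()
def make_cfg():
    def _make(**kw):
        return EnsembleConfig(**kw)
    return _make
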