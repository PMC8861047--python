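import numpy as np
import pytest

from placemol.conditioning import ConditionSpec
from placemol.model import AtomPlacementModel
from placemol.representation import ModelConfig


@pytest.fixture(scope="session")
def tiny_model():
    """A tiny untrained model with one scalar condition (HCNOF vocabulary)."""
    spec = ConditionSpec(name="target", kind="scalar", lam_min=0.0,
                         lam_max=10.0, d_omega=1.0, widths=(16, 16))
    cfg = ModelConfig.tiny(conditions=(spec,))
    return AtomPlacementModel.create(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
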