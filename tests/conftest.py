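import numpy as np
import pytest

from retclust.synth import LayerEffectModel
from retclust.types import ParticipantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ref_participant():
    """A reference-demographics participant: female, age at ref, plano."""
    return ParticipantRecord(pid="REF", age=50.0, sex="F", se=0.0)


@pytest.fixture
def clean_gcipl_model():
    """GCIPL effect model with all randomness switched off."""
    return LayerEffectModel(
        "GCIPL", age_slope=-0.112, se_slope=0.513, sex_offset=0.0,
        noise_sd=0.0, individual_sd=0.0,
    )
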