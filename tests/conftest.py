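import numpy as np
import pytest

import mstates as ms
from mstates.cluster import TemplateSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 1-s, 100 Hz random recording."""
    mont = ms.ChannelMontage(("Fz", "Cz", "Pz", "Oz"))
    return ms.EEGRecording(data=rng.normal(0.0, 20.0, (4, 100)), rate=100.0, montage=mont)


@pytest.fixture(scope="session")
def sim_k4():
    """One simulated 10-s recording with 4 planted classes at SNR 5."""
    cfg = ms.SynthConfig(K=4, length=10.0, snr=5.0, seed=21)
    rec, truth = ms.simulate(cfg)
    return ms.average_reference(rec), truth


def template_set(templates: np.ndarray) -> TemplateSet:
    """Wrap raw planted templates for backfitting."""
    K = templates.shape[0]
    return TemplateSet(
        templates=templates,
        labels=np.zeros(0, dtype=int),
        per_class_gev=np.zeros(K),
        total_gev=0.0,
    )


@pytest.fixture
def wrap_templates():
    return template_set
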