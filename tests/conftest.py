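import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import memepsp as mp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def uniform_bg():
    return mp.BackgroundModel.uniform()


@pytest.fixture
def skewed_bg():
    return mp.BackgroundModel.zero_order(np.array([0.4, 0.3, 0.2, 0.1]))


@pytest.fixture
def toy_seqs():
    return mp.SequenceSet.from_strings(
        ["ACGTACGTAC", "TTGACAGCTA", "CCCTGACTGG"])


@pytest.fixture
def planted_easy():
    """A strong planted motif in every sequence (easy recovery fixture)."""
    motif = mp.weak_motif(8, seed=11, dominant=0.95)
    spec = mp.PlantSpec(motif=motif, n=15, length=80, site_fraction=1.0,
                        seed=11)
    seqs, truth, _ = mp.generate_dataset(spec)
    return seqs, truth, motif
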