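import numpy as np
import pytest

from breathscreen.cohort import CANCER, HEALTHY, VOCTable


def make_table(conc, labels, voc_names=None, stage=None, origin=None,
               ids=None):
    """Hand-rolled VOCTable helper for small test cohorts."""
    conc = np.asarray(conc, float)
    voc_names = voc_names or [f"v{j}" for j in range(conc.shape[1])]
    ids = ids or [f"s{i}" for i in range(conc.shape[0])]
    return VOCTable(voc_names=voc_names, concentrations=conc,
                    labels=np.asarray(labels, object), sample_ids=ids,
                    stage=stage, origin=origin)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """4 cancer + 3 healthy samples over 3 VOCs, clearly separated."""
    conc = [[10, 1, 5], [12, 2, 5], [11, 1, 6], [13, 3, 5],
            [2, 1, 5], [3, 2, 6], [1, 1, 5]]
    labels = [CANCER] * 4 + [HEALTHY] * 3
    return make_table(conc, labels)


@pytest.fixture
def random_table(rng):
    """30-sample random cohort over 5 VOCs (no class signal)."""
    conc = rng.lognormal(mean=2.0, sigma=0.7, size=(30, 5))
    labels = [CANCER] * 18 + [HEALTHY] * 12
    return make_table(conc, labels)
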