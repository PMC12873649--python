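import numpy as np
import pytest

from pridetrial.data import TrialData


@pytest.fixture
def toy_data():
    """3 patients x 3 doses with a mix of outcomes and a down-retreat cell."""
    y = np.array([[0, 0, 1], [0, 1, 0], [0, 0, 0]], dtype=np.int8)
    treated = np.array(
        [[1, 1, 1], [0, 1, 1], [1, 0, 0]], dtype=bool
    )
    z = np.where(treated, 1, 0).astype(np.int8)
    z[1, 1] = 2  # patient 2 was down-retreated at dose 2
    return TrialData(y=y, treated=treated, assign_type=z)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_trial_data(rng, n=6, K=4, p_treat=0.5, with_z2=False):
    """Random valid TrialData: <= 3 treated doses per patient."""
    treated = np.zeros((n, K), dtype=bool)
    y = np.zeros((n, K), dtype=np.int8)
    z = np.zeros((n, K), dtype=np.int8)
    for i in range(n):
        doses = rng.choice(K, size=rng.integers(0, 4), replace=False)
        for k in doses:
            treated[i, k] = True
            y[i, k] = rng.random() < 0.4
            z[i, k] = 2 if (with_z2 and rng.random() < 0.3) else 1
    return TrialData(y=y, treated=treated, assign_type=z)
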