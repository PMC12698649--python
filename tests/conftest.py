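import numpy as np
import pandas as pd
import pytest

from vrcpt.preprocess import EpochSet


@pytest.fixture(scope="session")
def montage():
    from vrcpt.montage import make_montage

    return make_montage()


def build_epochset(data, sfreq=1000.0, ch_names=("Cz",), kind="target",
                   condition="N-D", pre_ms=200.0):
    """Assemble an EpochSet directly from an (n_ep, n_ch, n_samp) array."""
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, n_samp = data.shape
    pre = int(pre_ms * sfreq / 1000.0)
    times = (np.arange(n_samp) - pre) * 1000.0 / sfreq
    meta = pd.DataFrame({
        "onset_ms": np.arange(n_ep) * 1500.0,
        "kind": [kind] * n_ep,
        "condition": [condition] * n_ep,
        "participant": [0] * n_ep,
    })
    return EpochSet(data=data, times_ms=times, sfreq=sfreq,
                    ch_names=tuple(ch_names), meta=meta)


@pytest.fixture
def make_epochs():
    return build_epochset


@pytest.fixture(scope="session")
def erp_features():
    """Full-scale P300 recovery run (66 participants, 6 midline electrodes,
    150 target epochs per condition, 1000 Hz), shared across tests."""
    from vrcpt.pipeline import erp_recovery_run

    return erp_recovery_run(seed=0)
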