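import numpy as np
import pytest

import earsleep as es


@pytest.fixture
def rng():
    return np.random.default_rng(20210630)


@pytest.fixture
def small_recording(rng):
    """Eleven-channel recording (R1–R8, Fpz, EOG_L, EOG_R) of white noise."""
    labels = tuple(f"R{i}" for i in range(1, 9)) + ("Fpz", "EOG_L", "EOG_R")
    data = rng.normal(0, 25, (11, 2500))
    return es.Recording(labels, data, fs=250.0)


@pytest.fixture(scope="session")
def bundled():
    """The three published confusion matrices shipped with the package."""
    return {name: es.bundled_confusion(name) for name in
            ("fpz_eog_test_retest", "fpz_eog_vs_ceegrid", "fpz_eog_vs_ceegrid_eog")}
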