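import logging

import numpy as np
import pytest

from qthf import BeatTemplateParams, generate_beat, generate_record

# silence per-patient lead warnings during bulk runs
logging.getLogger("qthf").setLevel(logging.ERROR)


@pytest.fixture
def default_params():
    return BeatTemplateParams()


@pytest.fixture
def clean_beat(default_params):
    """One clean template beat (EcgRecord, QtSegment) at 1 kHz."""
    return generate_beat(default_params)


@pytest.fixture
def signal_rms_mv(clean_beat):
    rec, _ = clean_beat
    return float(np.sqrt(np.mean(rec.lead("V1") ** 2)) / 1e6)


@pytest.fixture
def clean_record(default_params):
    """10-beat clean record plus per-beat ground-truth segments."""
    return generate_record(default_params, n_beats=10)
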