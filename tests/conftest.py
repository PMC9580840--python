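import numpy as np
import pytest

from hydrolevel import HydropathyProfile, SequenceRecord, load_scale


@pytest.fixture(scope="session")
def mz():
    return load_scale("MZ")


@pytest.fixture(scope="session")
def kd():
    return load_scale("KD")


def make_profile(values, start=1, sequence_id="toy", scale_name="MZ", window=1):
    """Wrap a bare value list in a HydropathyProfile for levelset tests."""
    values = np.asarray(values, dtype=float)
    return HydropathyProfile(
        sequence_id=sequence_id,
        scale_name=scale_name,
        window=window,
        positions=np.arange(start, start + len(values)),
        values=values,
    )


@pytest.fixture
def toy_record():
    # 11 residues spanning hydrophobic and hydrophilic extremes
    return SequenceRecord(id="toy11", residues="IVLFCMAGTSW")
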