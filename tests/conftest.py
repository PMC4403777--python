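import pytest

from methpanel import ReferenceRegion, SimTruth


@pytest.fixture
def small_ref() -> ReferenceRegion:
    # CpG C at 1 and 5, non-CpG C at 7
    return ReferenceRegion.from_sequence("ACGATCGC")


@pytest.fixture
def default_truth() -> SimTruth:
    return SimTruth(seed=0)
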