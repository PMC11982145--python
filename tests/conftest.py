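import matplotlib
import pytest

matplotlib.use("Agg")

from dilishift.synthetic import study1_fixture, study2_fixture
from dilishift.trial_data import derive_profiles


@pytest.fixture(scope="session")
def study1():
    records, manifest = study1_fixture()
    return records, manifest, derive_profiles(records, manifest)


@pytest.fixture(scope="session")
def study2():
    records, manifest = study2_fixture()
    return records, manifest, derive_profiles(records, manifest)
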