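import pytest

from rnapir.synthetic_data import SyntheticConfig, generate_dataset, make_worked_fixture


@pytest.fixture(scope="session")
def worked():
    """Hand-written 12-PIR dataset with eye-enumerable flags."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_dir(tmp_path_factory):
    """The worked fixture written out in the on-disk formats."""
    d = tmp_path_factory.mktemp("worked")
    make_worked_fixture(d)
    return d


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small generated dataset shared by pipeline-level tests."""
    d = tmp_path_factory.mktemp("synth")
    cfg = SyntheticConfig(seed=11, n_pirs=1500)
    truth = generate_dataset(cfg, d)
    return d, cfg, truth
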