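import pytest

from talenscan import make_fixture_suite


@pytest.fixture(scope="session")
def suite42():
    """The seed-42 synthetic fixture bundle used across the suite."""
    return make_fixture_suite(42)


@pytest.fixture(scope="session")
def suite42_dir(tmp_path_factory):
    """The same bundle written to disk for CLI-level tests."""
    out = tmp_path_factory.mktemp("fixture42") / "bundle"
    make_fixture_suite(42, out_dir=out)
    return out
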