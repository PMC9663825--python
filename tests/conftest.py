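import pytest

from fairfmt import load_registry
from fairfmt.fixtures import FixtureSpec, generate_bundle


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def make_bundle(tmp_path):
    """Factory for generated bundles in a temp directory."""

    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        out = tmp_path / f"bundle{counter['n']}"
        spec = FixtureSpec(**kwargs)
        return generate_bundle(spec, out)

    return _make
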