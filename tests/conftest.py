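from pathlib import Path

import pytest

from txsum import synthetic

GOLDEN_DIR = Path(__file__).parent / "data" / "canonical"


@pytest.fixture(scope="session")
def canonical(tmp_path_factory):
    """The canonical small fixture (3 genes / 6 transcripts / 2 samples /
    4 bootstraps, seed 42), regenerated once per session with every on-disk
    dialect including the binary ones."""
    out = tmp_path_factory.mktemp("canonical_fixture")
    gt = synthetic.generate(synthetic.CANONICAL_SPEC, out)
    return gt, out


@pytest.fixture(scope="session")
def canonical_gt(canonical):
    return canonical[0]


@pytest.fixture(scope="session")
def canonical_dir(canonical):
    return canonical[1]


@pytest.fixture(scope="session")
def golden_dir():
    return GOLDEN_DIR
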