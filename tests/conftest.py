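import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from orthosplice.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Default small two-species fixture (200 genes, 3 replicates)."""
    return simulate_bundle(SimConfig(n_genes=200, seed=11))


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    from orthosplice.simulate import write_fixture_bundle
    directory = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_bundle, directory)
    return directory
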