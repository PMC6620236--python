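import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from bmcscan.simulate import generate_reference_set


@pytest.fixture(scope="session")
def bundle():
    """One synthetic reference bundle shared across the whole suite."""
    return generate_reference_set(11)


@pytest.fixture(scope="session")
def shell_profiles(bundle):
    from bmcscan.shell import build_shell_profiles

    return build_shell_profiles(bundle.seed_alignments)
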