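import pytest

from crcguide.skeleton import build_skeleton, reference_skeleton


@pytest.fixture(scope="session")
def skeleton():
    """The packaged reference ruleset."""
    return reference_skeleton()


@pytest.fixture()
def skeleton_doc():
    """A fresh, mutable copy of the skeleton document for defect injection."""
    return build_skeleton()
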