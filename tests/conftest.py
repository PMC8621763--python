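import hypothesis
import pytest

import doseline as dl

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def curve():
    return dl.DoseResponseCurve()


@pytest.fixture(scope="session")
def seg_config():
    return dl.SegmentationConfig()


@pytest.fixture(scope="session")
def segment_table(seg_config):
    """Full-precision table recomputed by the segmentation procedure."""
    return dl.build_segment_table(seg_config)


@pytest.fixture(scope="session")
def published_table():
    """The rounded four-interval table as published."""
    return dl.reference_segment_table()
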