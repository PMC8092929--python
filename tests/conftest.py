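import numpy as np
import pytest

from fhx.preprocess import segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def doc():
    """A small two-paragraph note exercising the main sentence shapes."""
    text = (
        "Mrs. Williams' mother is alive and well. "
        "Her mother's sister has arthritis.\n\n"
        "Her father died at age 62 of heart disease. "
        "Her paternal grandmother had diabetes type 2."
    )
    return segment("note1", text)


def make_doc(doc_id, text):
    return segment(doc_id, text)
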