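"""Shared fixtures: one synthetic genome per session plus the published table."""

import pytest

from mitochar.datasets import lepidoptera_composition, reference_annotation
from mitochar.synthetic_data import SimParams, generate_mitogenome


@pytest.fixture(scope="session")
def synthetic():
    """Default synthetic mitogenome: (genome, annotation, ground truth)."""
    return generate_mitogenome(SimParams(seed=1))


@pytest.fixture(scope="session")
def ref_table():
    """The published C. menciana annotation table, verbatim."""
    return reference_annotation()


@pytest.fixture(scope="session")
def composition_table():
    """The published 17-species composition/skew comparison."""
    return lepidoptera_composition()
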