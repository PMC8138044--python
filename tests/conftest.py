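"""Shared fixtures: tiny hand-built inputs plus the study label maps."""

import numpy as np
import pytest

from nodkey.alignment import AlleleAlignment
from nodkey.studydata import load_study_labels


@pytest.fixture(scope="session")
def study_labels():
    """(docking, md, thermo) pass/fail maps of the published outcomes."""
    return load_study_labels()


@pytest.fixture()
def toy_alignment():
    """4 sequences x 10 columns, variants planted at columns 3 and 7."""
    seqs = (
        "AACAAAGAAA",
        "AADAAAGAAA",
        "AACAAAHAAA",
        "AADAAAHAAA",
    )
    ids = tuple(f"s{i}" for i in range(4))
    groups = {ids[0]: "g1", ids[1]: "g1", ids[2]: "g2", ids[3]: "g2"}
    return AlleleAlignment(ids=ids, sequences=seqs, groups=groups)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
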