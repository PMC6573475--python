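import numpy as np
import pytest
from hypothesis import settings

from msypop import synth
from msypop.io import HaplotypeAlignment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_alignment() -> HaplotypeAlignment:
    """Two populations of 4, hand-picked sequences over 6 sites."""
    seqs = [
        "AAAAAA",
        "AAAAAT",
        "AAAATT",
        "AAAAAA",
        "TTAAAA",
        "TTAAAT",
        "TTTAAA",
        "TTAAAA",
    ]
    return HaplotypeAlignment(
        sample_ids=[f"s{i}" for i in range(8)],
        populations=["P1"] * 4 + ["P2"] * 4,
        sites=np.array([list(s) for s in seqs]),
        locus_length_bp=6,
    )


@pytest.fixture(scope="session")
def small_study():
    """One fixed synthetic study shared across structural tests."""
    design = synth.StudyDesign(
        n_populations={"AA": 3, "TK": 3, "ST": 2},
        samples_per_population=10,
        seed=42,
    )
    return synth.generate_study(design)
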