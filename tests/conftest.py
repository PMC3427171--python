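import numpy as np
import pytest

from splitscan.simulate import gen_score_profile, random_sequence


@pytest.fixture(scope="session")
def parent_137():
    """Deterministic 137-residue synthetic parent chain."""
    return random_sequence(137, seed=42)


@pytest.fixture(scope="session")
def npu_like_profile():
    """137-residue score profile with planted favorable maxima at the three
    sites used throughout the analysis (12, 36, 102)."""
    return gen_score_profile(
        137,
        peaks=[(12, 0.55, 3.0), (36, 0.55, 3.0), (102, 0.5, 3.0)],
        baseline=0.3,
        noise_sd=0.0,
        seed=7,
        protein_id="npu_synthetic",
    )
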