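import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cuic import MotifHit
from cuic.simulate import SimulationConfig, gen_transcripts


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7, n_rp=40, n_nonrp=60)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """A small planted-motif transcript cohort with its truth table."""
    return gen_transcripts(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


def make_hit(start: int, L: int, tid: str = "tx", word: str = "TCTTTTCC") -> MotifHit:
    return MotifHit(
        transcript_id=tid,
        start=start,
        end=start + 8,
        matched_seq=word,
        dist_to_start_codon=L - (start + 8),
    )
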