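import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mosste.simulate import (
    FamilySpec,
    GenomeSimConfig,
    gen_te_genome,
    gen_transcript_set,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_genome(seed: int = 3):
    """Two-family genome used across classification tests: one Gypsy-like
    LTR family and one Mariner-like DNA family, fragments outnumbering
    full copies."""
    return gen_te_genome(
        GenomeSimConfig(
            families=[
                FamilySpec("RLG_A", n_full=3, n_fragments=8, n_solo_ltr=3),
                FamilySpec(
                    "PpTc_B",
                    te_class="II",
                    superfamily="Mariner",
                    n_full=2,
                    n_fragments=4,
                    n_solo_ltr=0,
                    internal_len=2500,
                ),
            ],
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def bundle():
    return small_genome()


@pytest.fixture(scope="session")
def decoy_set(bundle):
    """One transcript of every category plus an extra genuine one."""
    plan = {
        "genuine_te": 2,
        "te_fragment": 3,
        "solo_ltr_readthrough": 1,
        "antisense": 1,
        "chimeric": 1,
        "gene": 1,
    }
    return gen_transcript_set(bundle, plan, seed=5)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
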