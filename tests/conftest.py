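import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phylodemog.alignment import SampleTable, collapse_haplotypes
from phylodemog.mismatch import simulate_expansion_alignment
from phylodemog.synthetic import generate, get_preset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_dataset():
    """One study-shaped synthetic dataset (262 ind, 22 pops, 5 groups)."""
    return generate(get_preset("study_shape", seed=3))


@pytest.fixture(scope="session")
def expansion_aln():
    """A sample drawn under a clean sudden expansion (tau=5)."""
    return simulate_expansion_alignment(
        40, 1248, 5.0, 0.5, 60.0, rng=np.random.default_rng(2024)
    )


@pytest.fixture()
def six_sequence_fixture():
    """Six sequences, three populations, two groups; used for exact checks."""
    seqs = {
        "i1": "AAAA", "i2": "AAAT", "i3": "AATT",
        "i4": "AATA", "i5": "TTTT", "i6": "TTTA",
    }
    pop = {"i1": "p1", "i2": "p1", "i3": "p2", "i4": "p2", "i5": "p3", "i6": "p3"}
    aln = collapse_haplotypes(seqs.items(), pop)
    table = SampleTable(
        pd.DataFrame(
            {
                "individual": list(pop),
                "population": list(pop.values()),
                "group": ["g1", "g1", "g1", "g1", "g2", "g2"],
            }
        )
    )
    return seqs, pop, aln, table
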