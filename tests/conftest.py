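import pytest

import geroscore as gs

FIXED_CLOCK = "2026-01-01T00:00:00+00:00"


@pytest.fixture(scope="session")
def cfg():
    return gs.EvaluationConfig()


@pytest.fixture(scope="session")
def sams1_kb():
    return gs.plant_worked_example_sams1()


@pytest.fixture(scope="session")
def synth_kb():
    """60 random-mask genes (published satisfaction proportions), seed 11."""
    kb, ledger = gs.generate(gs.GeneratorSpec(n_genes=60, seed=11))
    return kb, ledger


@pytest.fixture(scope="session")
def single_bit_kb():
    """Nine genes, the i-th satisfying exactly evaluation function i+1."""
    profiles = [gs.make_profile(i, tuple(j == i for j in range(9)))
                for i in range(9)]
    kb = gs.KnowledgeBase()
    for p in profiles:
        gs.plant_profile(kb, p)
    return kb, profiles
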