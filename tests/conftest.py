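"""Shared fixtures: seeded simulations reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from nanoterm.simulate import SimParams, make_draft, simulate_genome, simulate_reads

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The full study-condition simulation (200 chromosomes, 60x)."""
    params = SimParams(seed=101)
    truth = simulate_genome(params)
    pairs, provenance = simulate_reads(truth)
    draft, draft_table = make_draft(truth)
    return {"params": params, "truth": truth, "pairs": pairs,
            "provenance": provenance, "draft": draft,
            "draft_table": draft_table}


@pytest.fixture(scope="session")
def small_sim():
    """A 30-chromosome simulation for cheaper integration tests."""
    params = SimParams(n_chromosomes=30, seed=5)
    truth = simulate_genome(params)
    pairs, provenance = simulate_reads(truth)
    draft, draft_table = make_draft(truth)
    return {"params": params, "truth": truth, "pairs": pairs,
            "provenance": provenance, "draft": draft,
            "draft_table": draft_table}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
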