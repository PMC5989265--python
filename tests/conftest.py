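"""Shared fixtures: one simulated reference reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from splicestage.datamodel import ReferenceAtlas
from splicestage.staging import SplicescopeStager
from splicestage.synthetic import simulate_reference

REF_SEED = 7
REF_N_EXONS = 600


@pytest.fixture(scope="session")
def ref_sim():
    """(counts, psi, truth) for a mid-sized simulated cortex reference."""
    return simulate_reference(n_exons=REF_N_EXONS, seed=REF_SEED)


@pytest.fixture(scope="session")
def truth(ref_sim):
    return ref_sim[2]


@pytest.fixture(scope="session")
def module_exons(truth):
    mod = truth.module_of()
    return mod[mod.str.startswith(("M1", "M2"))].index


@pytest.fixture(scope="session")
def atlas(ref_sim, module_exons) -> ReferenceAtlas:
    """Reference atlas over the M1/M2 module exons (estimated Ψ)."""
    _, psi, _ = ref_sim
    return ReferenceAtlas(psi.subset_exons(module_exons).complete_rows())


@pytest.fixture(scope="session")
def stager(atlas) -> SplicescopeStager:
    return SplicescopeStager().fit(atlas)
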