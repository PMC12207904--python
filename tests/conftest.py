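import numpy as np
import pandas as pd
import pytest

from domstat import compute_traits
from domstat.formula_core import formulas_from_table
from domstat.synthetic import generate_study


@pytest.fixture(scope="session")
def study():
    """Small seeded synthetic study shared across test modules."""
    return generate_study(seed=7, n_molecules=250, n_dark=250, n_genera=50)


@pytest.fixture(scope="session")
def trait_table(study):
    return compute_traits(formulas_from_table(study["formulas"]))


@pytest.fixture(scope="session")
def mcd(study, trait_table):
    from domstat import build_dendrogram
    cols = ["mass", "o_c", "h_c", "ai_mod", "dbe", "nosc"]
    return build_dendrogram(trait_table=trait_table[cols], kind="MCD")
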