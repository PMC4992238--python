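"""Shared fixtures: the deterministic 6-drug toy landscape and its
hand-enumerated expected values.

The expected pair table below was worked out by hand from the toy
activity sets (intersection and symmetric-difference counts) and the
fixed chemical-similarity matrix; it is the oracle the pipeline is
checked against, independent of any package code.
"""

import numpy as np
import pandas as pd
import pytest

from activitycanyon import build_pair_weights, make_toy_fixture

# (drug_i, drug_j, c, s, d) for all 15 unordered pairs, by manual set
# arithmetic on the toy profiles:
#   D1={T0,T1,T2} D2={T1,T2,T3} D3={T0..T4} D4={T5} D5={} D6={T0,T5..T9}
TOY_EXPECTED = pd.DataFrame(
    [
        ("D1", "D2", 0.90, 2, 2),
        ("D1", "D3", 0.70, 3, 2),
        ("D1", "D4", 0.10, 0, 4),
        ("D1", "D5", 0.00, 0, 3),
        ("D1", "D6", 0.30, 1, 7),
        ("D2", "D3", 0.80, 3, 2),
        ("D2", "D4", 0.20, 0, 4),
        ("D2", "D5", 0.05, 0, 3),
        ("D2", "D6", 0.35, 0, 9),
        ("D3", "D4", 0.15, 0, 6),
        ("D3", "D5", 0.10, 0, 5),
        ("D3", "D6", 0.50, 1, 9),
        ("D4", "D5", 0.40, 0, 1),
        ("D4", "D6", 0.65, 1, 5),
        ("D5", "D6", 0.25, 0, 6),
    ],
    columns=["drug_i", "drug_j", "c", "s", "d"],
)

TOY_DEGREES = {"D1": 3, "D2": 3, "D3": 5, "D4": 1, "D5": 0, "D6": 6}


@pytest.fixture(scope="session")
def toy():
    net, chem = make_toy_fixture()
    return net, chem


@pytest.fixture(scope="session")
def toy_pairs(toy):
    net, chem = toy
    return build_pair_weights(net, chem)


@pytest.fixture(scope="session")
def toy_expected():
    return TOY_EXPECTED.copy()


def pair_lookup(df: pd.DataFrame) -> dict:
    """Map frozenset({drug_i, drug_j}) -> row for order-free comparison."""
    return {
        frozenset((r.drug_i, r.drug_j)): r for r in df.itertuples(index=False)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
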