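"""Seeded synthetic ensembles with the statistical structure of the model.

Two generation modes serve different testing needs:

* ``pair_sampler`` draws (c, s, d) pair weights directly and
  independently from the model marginals -- a truncated Pareto for c, a
  zero-inflated discrete power law for s and a geometric (discrete
  exponential) for d.  Because the axes are sampled independently, the
  degree identity d + 2s = deg_i + deg_j does NOT hold in this mode; it
  exists to exercise the probability machinery under exactly the
  independence assumption the closed forms rest on.

* ``bipartite_graph`` builds an actual drug-target network with
  heavy-tailed drug degrees, from which pair weights are derived by set
  arithmetic; this is the fixture for identity-sensitive tests.

All generators are deterministic given the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from activitycanyon.pair_network import ChemSimilarityMatrix, DrugTargetNetwork

logger = logging.getLogger(__name__)


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic drug ensemble.

    Marginal defaults are the constants fitted on the original drug
    ensemble: c ~ power law with exponent 3.6 above c_min = 0.004
    (truncated at 1), s ~ discrete power law with exponent 2.37 above
    s_min = 1 zero-inflated so that 90% of pairs share no target, and
    d ~ discrete exponential with rate 0.17 from d_min = 0.
    """

    n_drugs: int = 100
    n_targets: int = 200
    gamma_c: float = 3.6
    c_min: float = 0.004
    alpha_s: float = 2.37
    s_min: int = 1
    lambda_d: float = 0.17
    d_min: int = 0
    zero_fraction_s: float = 0.9
    degree_exponent: float = 2.5
    seed: int = 0
    mode: str = "pair_sampler"
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("pair_sampler", "bipartite_graph"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gamma_c <= 1 or self.alpha_s <= 1 or self.degree_exponent <= 1:
            raise ValueError("power-law exponents must exceed 1")
        if self.lambda_d <= 0:
            raise ValueError("exponential rate must be positive")
        if not (0 <= self.zero_fraction_s < 1):
            raise ValueError("zero_fraction_s must lie in [0, 1)")
        if self.n_drugs < 2 or self.n_targets < 2:
            raise ValueError("need at least 2 drugs and 2 targets")
        if not (0 < self.c_min < 1):
            raise ValueError("c_min must lie in (0, 1)")

    @property
    def resolved_n_pairs(self) -> int:
        if self.n_pairs is not None:
            return self.n_pairs
        return self.n_drugs * (self.n_drugs - 1) // 2


def _sample_truncated_pareto(
    rng: np.random.Generator, n: int, exponent: float, x_min: float, x_max: float
) -> np.ndarray:
    """Inverse-CDF draws from a power law on [x_min, x_max]."""
    u = rng.random(n)
    e = 1.0 - exponent
    t = (x_max / x_min) ** e
    return x_min * (1.0 - u * (1.0 - t)) ** (1.0 / e)


def sample_pair_weights(spec: EnsembleSpec) -> pd.DataFrame:
    """Draw a pair-weight table from the model marginals under independence.

    Returns the standard pair-table layout; the degree columns are NaN
    because no underlying network exists in this mode.
    """
    if spec.mode != "pair_sampler":
        raise ValueError("sample_pair_weights requires mode='pair_sampler'")
    rng = np.random.default_rng(spec.seed)
    n = spec.resolved_n_pairs

    c = _sample_truncated_pareto(rng, n, spec.gamma_c, spec.c_min, 1.0)

    # s: discrete power law on {s_min, s_min+1, ...}, zero-inflated
    s = sstats.zipf.rvs(spec.alpha_s, loc=spec.s_min - 1, size=n, random_state=rng)
    zero = rng.random(n) < spec.zero_fraction_s
    s = np.where(zero, 0, s).astype(int)

    # d: geometric with success prob 1 - exp(-lambda), the discrete
    # analog of the exponential on integer counts, shifted by d_min
    d = rng.geometric(1.0 - np.exp(-spec.lambda_d), size=n) - 1 + spec.d_min

    names = np.array([f"p{i:07d}" for i in range(2 * n)], dtype=object)
    return pd.DataFrame(
        {
            "drug_i": names[0::2],
            "drug_j": names[1::2],
            "c": c,
            "s": s,
            "d": d.astype(int),
            "deg_i": np.nan,
            "deg_j": np.nan,
        }
    )


def generate_bipartite(spec: EnsembleSpec, preferential: bool = False) -> DrugTargetNetwork:
    """Random bipartite activity network with heavy-tailed drug degrees.

    Drug degrees are discrete power-law draws (exponent
    ``degree_exponent``); degrees exceeding the target universe are
    resampled a few times, then capped with a logged warning.  Targets
    are attached uniformly without replacement, or preferentially
    (weight proportional to current target degree + 1) when
    ``preferential`` is set.
    """
    if spec.mode != "bipartite_graph":
        raise ValueError("generate_bipartite requires mode='bipartite_graph'")
    rng = np.random.default_rng(spec.seed)
    degrees = sstats.zipf.rvs(spec.degree_exponent, size=spec.n_drugs, random_state=rng)
    for _ in range(10):
        over = degrees > spec.n_targets
        if not over.any():
            break
        degrees[over] = sstats.zipf.rvs(
            spec.degree_exponent, size=int(over.sum()), random_state=rng
        )
    over = degrees > spec.n_targets
    if over.any():
        logger.warning("capping %d drug degree(s) at n_targets=%d", over.sum(), spec.n_targets)
        degrees[over] = spec.n_targets

    activity = np.zeros((spec.n_drugs, spec.n_targets), dtype=np.int8)
    target_load = np.ones(spec.n_targets)
    for i, k in enumerate(degrees):
        if preferential:
            p = target_load / target_load.sum()
            chosen = rng.choice(spec.n_targets, size=int(k), replace=False, p=p)
            target_load[chosen] += 1
        else:
            chosen = rng.choice(spec.n_targets, size=int(k), replace=False)
        activity[i, chosen] = 1
    drug_ids = [f"drug{i:05d}" for i in range(spec.n_drugs)]
    target_ids = [f"prot{k:05d}" for k in range(spec.n_targets)]
    return DrugTargetNetwork(drug_ids, target_ids, activity)


def random_similarity_matrix(
    n_drugs: int, seed: int, gamma_c: float = 1.8, c_min: float = 0.004
) -> ChemSimilarityMatrix:
    """Symmetric chemical-similarity matrix with power-law-distributed
    off-diagonal entries and a unit diagonal.

    The default exponent is flatter than the fitted marginal of the
    large ensemble so that networks of a few dozen drugs still populate
    the high-similarity regions the regional analyses study.
    """
    rng = np.random.default_rng(seed)
    n_off = n_drugs * (n_drugs - 1) // 2
    vals = _sample_truncated_pareto(rng, n_off, gamma_c, c_min, 1.0)
    mat = np.eye(n_drugs)
    iu, ju = np.triu_indices(n_drugs, k=1)
    mat[iu, ju] = vals
    mat[ju, iu] = vals
    drug_ids = [f"drug{i:05d}" for i in range(n_drugs)]
    return ChemSimilarityMatrix(drug_ids, mat)


# Deterministic 6-drug / 10-target fixture.  The activity sets are small
# enough that s and d for all 15 pairs can be enumerated by hand; the
# expected values live beside the oracle tests.
_TOY_PROFILES: dict[str, set[int]] = {
    "D1": {0, 1, 2},
    "D2": {1, 2, 3},
    "D3": {0, 1, 2, 3, 4},
    "D4": {5},
    "D5": set(),
    "D6": {0, 5, 6, 7, 8, 9},
}

_TOY_C: dict[tuple[str, str], float] = {
    ("D1", "D2"): 0.9,
    ("D1", "D3"): 0.7,
    ("D1", "D4"): 0.1,
    ("D1", "D5"): 0.0,
    ("D1", "D6"): 0.3,
    ("D2", "D3"): 0.8,
    ("D2", "D4"): 0.2,
    ("D2", "D5"): 0.05,
    ("D2", "D6"): 0.35,
    ("D3", "D4"): 0.15,
    ("D3", "D5"): 0.1,
    ("D3", "D6"): 0.5,
    ("D4", "D5"): 0.4,
    ("D4", "D6"): 0.65,
    ("D5", "D6"): 0.25,
}


def make_toy_fixture() -> tuple[DrugTargetNetwork, ChemSimilarityMatrix]:
    """Deterministic 6-drug, 10-target network plus a fixed c matrix.

    The c values span [0, 1] (including an exact 0 and the unit
    diagonal); one drug has an empty activity profile to exercise the
    degree-zero edge case.
    """
    drug_ids = sorted(_TOY_PROFILES)
    target_ids = [f"T{k}" for k in range(10)]
    activity = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    for i, drug in enumerate(drug_ids):
        for k in _TOY_PROFILES[drug]:
            activity[i, k] = 1
    net = DrugTargetNetwork(drug_ids, target_ids, activity)

    cmat = np.eye(len(drug_ids))
    for (a, b), v in _TOY_C.items():
        ia, ib = drug_ids.index(a), drug_ids.index(b)
        cmat[ia, ib] = cmat[ib, ia] = v
    chem = ChemSimilarityMatrix(drug_ids, cmat)
    return net, chem
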