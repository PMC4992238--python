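"""Drug-drug pair weights (c, s, d) from a bipartite activity network.

The central object is the long-form pair-weight table: one row per
unordered drug pair ``i < j`` with the chemical similarity ``c``, the
number of common targets ``s``, the number of targets on which the pair
differs ``d``, and the two drug degrees.  Targets on which neither drug
is active contribute to none of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from activitycanyon.errors import InputConsistencyError

PAIR_COLUMNS = ["drug_i", "drug_j", "c", "s", "d", "deg_i", "deg_j"]


@dataclass
class ActivityProfile:
    """Binary activity profile of one drug: the set of targets it is active on.

    Target indices refer to positions in a shared target universe of size
    ``n_targets``; two profiles are comparable only over the same universe.
    """

    drug_id: str
    targets: frozenset[int]
    n_targets: int

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        if self.targets and (min(self.targets) < 0 or max(self.targets) >= self.n_targets):
            raise InputConsistencyError(
                f"profile {self.drug_id!r}: target index outside universe of size {self.n_targets}"
            )

    @property
    def degree(self) -> int:
        return len(self.targets)


@dataclass
class DrugTargetNetwork:
    """Bipartite drug-target activity network with a binary incidence matrix.

    ``activity[i, k] == 1`` iff drug ``i`` is active on target ``k``.
    """

    drug_ids: list[str]
    target_ids: list[str]
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity)
        n, m = self.activity.shape
        if n != len(self.drug_ids) or m != len(self.target_ids):
            raise InputConsistencyError("activity matrix shape does not match id lists")
        if len(set(self.drug_ids)) != n:
            raise InputConsistencyError("duplicate drug ids")
        if len(set(self.target_ids)) != m:
            raise InputConsistencyError("duplicate target ids")
        vals = np.unique(self.activity)
        if not np.all(np.isin(vals, [0, 1])):
            raise InputConsistencyError("activity entries must be exactly 0 or 1")
        self.activity = self.activity.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def degrees(self) -> np.ndarray:
        """Number of targets per drug (row sums)."""
        return self.activity.sum(axis=1).astype(int)

    def profile(self, drug_id: str) -> ActivityProfile:
        i = self.drug_ids.index(drug_id)
        targets = frozenset(np.flatnonzero(self.activity[i]).tolist())
        return ActivityProfile(drug_id, targets, self.n_targets)

    def profiles(self) -> list[ActivityProfile]:
        return [self.profile(d) for d in self.drug_ids]


@dataclass
class ChemSimilarityMatrix:
    """Symmetric pairwise chemical-similarity matrix with values in [0, 1]."""

    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.drug_ids)
        if self.values.shape != (n, n):
            raise InputConsistencyError("similarity matrix is not square over drug ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise InputConsistencyError("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise InputConsistencyError("similarity values outside [0, 1]")

    def get(self, drug_a: str, drug_b: str) -> float:
        ia = self.drug_ids.index(drug_a)
        ib = self.drug_ids.index(drug_b)
        return float(self.values[ia, ib])

    @classmethod
    def from_fingerprints(cls, drug_ids: list[str], fps: np.ndarray) -> "ChemSimilarityMatrix":
        """Tanimoto matrix from an (n_drugs, n_bits) binary fingerprint array."""
        fps = np.asarray(fps, dtype=np.int64)
        inter = fps @ fps.T
        ones = fps.sum(axis=1)
        union = ones[:, None] + ones[None, :] - inter
        # all-zero vs all-zero fingerprints: union 0, similarity defined as 0
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        return cls(list(drug_ids), sim)


def _check_universe(profile_i: ActivityProfile, profile_j: ActivityProfile) -> None:
    if profile_i.n_targets != profile_j.n_targets:
        raise InputConsistencyError(
            "activity profiles are defined over different target universes "
            f"({profile_i.n_targets} vs {profile_j.n_targets} targets)"
        )


def compute_s(profile_i: ActivityProfile, profile_j: ActivityProfile) -> int:
    """Activity similarity: number of targets both drugs are active on.

    Targets on which neither drug is active are ignored, so ``s`` is the
    unnormalized Jaccard intersection of the two profiles.
    """
    _check_universe(profile_i, profile_j)
    return len(profile_i.targets & profile_j.targets)


def compute_d(profile_i: ActivityProfile, profile_j: ActivityProfile) -> int:
    """Activity variation: number of targets on which the drugs differ.

    This is the symmetric-difference count, equal to
    ``deg_i + deg_j - 2 * s``.
    """
    _check_universe(profile_i, profile_j)
    return len(profile_i.targets ^ profile_j.targets)


def tanimoto(fp_i: np.ndarray, fp_j: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary fingerprints.

    Two all-zero fingerprints are defined to have similarity 0 (the 0/0
    case carries no structural information).
    """
    a = np.asarray(fp_i).astype(bool)
    b = np.asarray(fp_j).astype(bool)
    if a.shape != b.shape:
        raise InputConsistencyError(f"fingerprint lengths differ: {a.size} vs {b.size}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def build_pair_weights(net: DrugTargetNetwork, chem: ChemSimilarityMatrix) -> pd.DataFrame:
    """Pair-weight table over all unordered drug pairs of the network.

    Returns a DataFrame with one row per pair ``i < j`` (in the network's
    drug order) and columns ``drug_i, drug_j, c, s, d, deg_i, deg_j``.
    The drug-id sets of the network and the similarity source must agree;
    ids are matched by value, not position.
    """
    if set(net.drug_ids) != set(chem.drug_ids):
        raise InputConsistencyError(
            "drug ids of the activity network and similarity matrix differ"
        )
    order = [chem.drug_ids.index(d) for d in net.drug_ids]
    cmat = chem.values[np.ix_(order, order)]

    act = net.activity.astype(np.int64)
    inter = act @ act.T  # s for every ordered pair
    deg = act.sum(axis=1)
    iu, ju = np.triu_indices(net.n_drugs, k=1)
    s = inter[iu, ju]
    d = deg[iu] + deg[ju] - 2 * s
    drug_arr = np.asarray(net.drug_ids, dtype=object)
    return pd.DataFrame(
        {
            "drug_i": drug_arr[iu],
            "drug_j": drug_arr[ju],
            "c": cmat[iu, ju],
            "s": s.astype(int),
            "d": d.astype(int),
            "deg_i": deg[iu].astype(int),
            "deg_j": deg[ju].astype(int),
        }
    )


def filter_chemical_window(pairs: pd.DataFrame, c1: float, c2: float) -> pd.DataFrame:
    """Rows of the pair table with chemical similarity in [c1, c2], inclusive."""
    if not (0 <= c1 <= c2 <= 1):
        raise ValueError(f"invalid chemical window [{c1}, {c2}]")
    mask = (pairs["c"] >= c1) & (pairs["c"] <= c2)
    return pairs.loc[mask].reset_index(drop=True)
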