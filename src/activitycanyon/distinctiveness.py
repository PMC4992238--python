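"""Region statistics and multi-level distinctiveness filtering.

A *distinctive* interaction is a chemically similar drug pair whose
activity similarity ``s`` falls below, or activity variation ``d`` rises
above, the regional average by some number ``n`` of standard deviations.
All statistics (mu, sigma) are computed from the pair data inside the
chemical window under study, never taken as fixed constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from activitycanyon.errors import DegenerateRegionError, InsufficientDataError
from activitycanyon.pair_network import filter_chemical_window

DEFAULT_GLOBAL_REGION = (0.3, 1.0)
DEFAULT_HIGH_SIMILARITY_REGION = (0.65, 1.0)


@dataclass
class RegionStats:
    """Mean and standard deviation of s and d over a chemical window."""

    region: tuple[float, float]
    mu_s: float
    sigma_s: float
    mu_d: float
    sigma_d: float
    n_pairs: int


@dataclass
class ThresholdSpec:
    """One distinctiveness criterion: measure, direction and n-sigma level.

    ``above`` selects ``measure >= mu + n*sigma``; ``below`` selects
    ``measure <= mu - n*sigma`` with the threshold floored at 0 (counts
    cannot be negative).  Both inequalities are inclusive.
    """

    measure: str  # "s" or "d"
    direction: str  # "above" or "below"
    n: float
    region: tuple[float, float]

    def __post_init__(self) -> None:
        if self.measure not in ("s", "d"):
            raise ValueError(f"measure must be 's' or 'd', got {self.measure!r}")
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if self.n < 0:
            raise ValueError("n multiplier must be >= 0")

    def threshold(self, stats: RegionStats) -> float:
        mu = stats.mu_s if self.measure == "s" else stats.mu_d
        sigma = stats.sigma_s if self.measure == "s" else stats.sigma_d
        if self.direction == "above":
            return mu + self.n * sigma
        return max(0.0, mu - self.n * sigma)


@dataclass
class DistinctiveNetwork:
    """Filtered drug-pair network; every edge satisfies the criterion.

    ``edges`` carries a ``level`` column: the largest integer n (on
    0..n_max) at which the edge still satisfies the criterion.
    """

    edges: pd.DataFrame
    criterion: ThresholdSpec
    stats: RegionStats

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """Undirected weighted graph for visualization/export (GraphML etc.)."""
        import networkx as nx

        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.drug_i, row.drug_j, c=float(row.c), s=int(row.s), d=int(row.d),
                level=int(row.level),
            )
        return g


def region_stats(pairs: pd.DataFrame, region: tuple[float, float]) -> RegionStats:
    """Mean/sd of s and d over pairs with c inside the (inclusive) region.

    Standard deviations are population-style (ddof=0), matching plain
    moment statistics of the pairs actually present.
    """
    sub = filter_chemical_window(pairs, *region)
    if len(sub) < 2:
        raise InsufficientDataError(
            f"region {region} holds {len(sub)} pair(s); need at least 2"
        )
    return RegionStats(
        region=(float(region[0]), float(region[1])),
        mu_s=float(sub["s"].mean()),
        sigma_s=float(sub["s"].std(ddof=0)),
        mu_d=float(sub["d"].mean()),
        sigma_d=float(sub["d"].std(ddof=0)),
        n_pairs=len(sub),
    )


def standardize(pairs: pd.DataFrame, stats: RegionStats) -> pd.DataFrame:
    """Pair table with standardized ``z_s`` and ``z_d`` columns appended.

    z = (value - mu) / sigma, using the supplied regional statistics; with
    those statistics the comparison of s and d reduces to above/below 0.
    """
    if stats.sigma_s == 0 or stats.sigma_d == 0:
        raise DegenerateRegionError("zero standard deviation; cannot standardize")
    out = pairs.copy()
    out["z_s"] = (out["s"] - stats.mu_s) / stats.sigma_s
    out["z_d"] = (out["d"] - stats.mu_d) / stats.sigma_d
    return out


def _satisfies(values: np.ndarray, spec: ThresholdSpec, stats: RegionStats, n: float) -> np.ndarray:
    mu = stats.mu_s if spec.measure == "s" else stats.mu_d
    sigma = stats.sigma_s if spec.measure == "s" else stats.sigma_d
    if spec.direction == "above":
        return values >= mu + n * sigma
    return values <= max(0.0, mu - n * sigma)


def filter_distinctive(
    pairs: pd.DataFrame,
    spec: ThresholdSpec,
    stats: RegionStats,
    n_max_level: int = 10,
) -> DistinctiveNetwork:
    """Drug pairs in the region that satisfy the distinctiveness criterion.

    Each emitted edge is annotated with its maximal integer level: the
    largest integer n <= ``n_max_level`` for which the (inclusive)
    inequality still holds.  An empty result is valid.
    """
    if spec.region != stats.region:
        raise ValueError("threshold spec and region statistics cover different regions")
    sub = filter_chemical_window(pairs, *spec.region)
    values = sub[spec.measure].to_numpy(dtype=float)
    keep = _satisfies(values, spec, stats, spec.n)
    sub = sub.loc[keep].copy()
    values = values[keep]
    levels = np.zeros(len(sub), dtype=int)
    for n in range(1, n_max_level + 1):
        ok = _satisfies(values, spec, stats, float(n))
        if not ok.any():
            break
        levels[ok] = n
    sub["level"] = levels
    return DistinctiveNetwork(edges=sub.reset_index(drop=True), criterion=spec, stats=stats)


def compare_filters(
    pairs: pd.DataFrame, region: tuple[float, float], n_max: int
) -> pd.DataFrame:
    """Counts of pairs selected by s-below vs d-above criteria for n = 0..n_max.

    Returns a table with, per level n, the number of pairs with
    s <= mu_s - n*sigma_s, the number with d >= mu_d + n*sigma_d, and the
    overlap selected by both.
    """
    stats = region_stats(pairs, region)
    sub = filter_chemical_window(pairs, *region)
    s = sub["s"].to_numpy(dtype=float)
    d = sub["d"].to_numpy(dtype=float)
    rows = []
    for n in range(n_max + 1):
        low_s = s <= max(0.0, stats.mu_s - n * stats.sigma_s)
        high_d = d >= stats.mu_d + n * stats.sigma_d
        rows.append(
            {
                "n": n,
                "count_s_below": int(low_s.sum()),
                "count_d_above": int(high_d.sum()),
                "overlap": int((low_s & high_d).sum()),
            }
        )
    return pd.DataFrame(rows)


def cross_magnitude_diagnostic(
    pairs: pd.DataFrame, region: tuple[float, float]
) -> float:
    """Fraction of above-average d weights exceeding the 75th percentile of
    below-average s weights, within the region.

    A descriptive comparison of the magnitude scales of the two filters;
    interpretation-level only (the underlying procedure admits variants).
    """
    stats = region_stats(pairs, region)
    sub = filter_chemical_window(pairs, *region)
    d_above = sub.loc[sub["d"] >= stats.mu_d, "d"].to_numpy(dtype=float)
    s_below = sub.loc[sub["s"] <= stats.mu_s, "s"].to_numpy(dtype=float)
    if d_above.size == 0 or s_below.size == 0:
        raise InsufficientDataError("diagnostic needs pairs on both sides of the averages")
    q75 = float(np.percentile(s_below, 75))
    return float((d_above > q75).mean())
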