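"""Statistical battery comparing the s and d distinctiveness measures.

Two paired tests are used.  McNemar's test compares, on the *same* drug
pairs within one chemical region, the proportion satisfying an
s-criterion against the proportion satisfying a d-criterion; only the
discordant cells enter the statistic.  A paired t-test compares two
vectors of exceedance probabilities sampled over the same n-sigma grid,
e.g. between two chemical regions.

The default battery runs six comparisons:

1-3. McNemar on s >= mu_s vs d >= mu_d in the regions [0.3, 1],
     [0.3, 0.65] and [0.65, 1] (is above-average variation more frequent
     than above-average similarity?).
4-5. Paired t on the exceedance-probability vectors of s (test 4) and d
     (test 5) between regions [0.3, 0.65] and [0.65, 1] (do the measures
     decay as chemical similarity grows?).
6.   McNemar on s <= mu_s vs d >= mu_d in [0.65, 1] (which measure is
     the sharper filter of rare distinctive pairs?).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from activitycanyon.distinctiveness import RegionStats, region_stats
from activitycanyon.errors import DegenerateRegionError, InsufficientDataError
from activitycanyon.pair_network import filter_chemical_window


@dataclass
class ContingencyTable:
    """Paired cross-classification of region pairs by two binary criteria.

    Rows: the first criterion (an s condition); columns: the second
    (a d condition).  ``n2`` and ``n3`` are the discordant cells:
    n2 = first only, n3 = second only.
    """

    n1: int  # both criteria hold
    n2: int  # first (s) criterion only
    n3: int  # second (d) criterion only
    n4: int  # neither

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    @property
    def p_first(self) -> float:
        """Marginal proportion satisfying the first criterion."""
        return (self.n1 + self.n2) / self.n

    @property
    def p_second(self) -> float:
        """Marginal proportion satisfying the second criterion."""
        return (self.n1 + self.n3) / self.n


@dataclass
class McNemarResult:
    chi2_stat: float
    p_chi2: float
    p_exact: float
    rho: float
    reject: bool
    alternative: str
    degenerate: bool = False


@dataclass
class PairedTResult:
    t_stat: float
    df: int
    p: float
    delta_mean: float
    sigma_delta: float
    n_samples: int
    alternative: str
    degenerate: bool = False


def build_contingency(
    pairs: pd.DataFrame,
    region: tuple[float, float],
    stats: RegionStats | None = None,
    s_condition: str = "above",
    d_condition: str = "above",
    n_s: float = 0.0,
    n_d: float = 0.0,
) -> ContingencyTable:
    """Cross-classify every region pair by an s- and a d-criterion.

    The default criteria are s >= mu_s and d >= mu_d (inclusive).  For
    the filter comparison, ``s_condition="below"`` uses s <= mu_s - n_s *
    sigma_s and ``d_condition="above"`` uses d >= mu_d + n_d * sigma_d.
    """
    sub = filter_chemical_window(pairs, *region)
    if len(sub) == 0:
        raise DegenerateRegionError(f"no pairs with c in {region}")
    if stats is None:
        stats = region_stats(pairs, region)
    s = sub["s"].to_numpy(dtype=float)
    d = sub["d"].to_numpy(dtype=float)
    if s_condition == "above":
        a = s >= stats.mu_s + n_s * stats.sigma_s
    else:
        a = s <= max(0.0, stats.mu_s - n_s * stats.sigma_s)
    if d_condition == "above":
        b = d >= stats.mu_d + n_d * stats.sigma_d
    else:
        b = d <= max(0.0, stats.mu_d - n_d * stats.sigma_d)
    return ContingencyTable(
        n1=int((a & b).sum()),
        n2=int((a & ~b).sum()),
        n3=int((~a & b).sum()),
        n4=int((~a & ~b).sum()),
    )


def _binom_tail(k: int, n: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/2) by direct summation."""
    if k <= 0:
        return 1.0
    total = sum(math.comb(n, j) for j in range(k, n + 1))
    return total / 2**n


def mcnemar(
    table: ContingencyTable, rho: float = 0.05, alternative: str = "n3_greater"
) -> McNemarResult:
    """McNemar's test on the discordant cells of a paired contingency table.

    The chi-square statistic is (n2 - n3)^2 / (n2 + n3) on 1 df (no
    continuity correction).  The exact p is the one-sided binomial tail
    P(X >= max-favored-count | n2 + n3, 1/2) summed directly; for the
    two-sided alternative it is doubled (capped at 1).  The rejection
    flag compares the exact p against ``rho``.
    """
    if alternative not in ("two_sided", "n2_greater", "n3_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m = table.n2 + table.n3
    if m == 0:
        return McNemarResult(
            chi2_stat=0.0, p_chi2=1.0, p_exact=1.0, rho=rho, reject=False,
            alternative=alternative, degenerate=True,
        )
    chi2 = (table.n2 - table.n3) ** 2 / m
    p_chi2 = float(sstats.chi2.sf(chi2, df=1))
    if alternative == "n3_greater":
        p_exact = _binom_tail(table.n3, m)
    elif alternative == "n2_greater":
        p_exact = _binom_tail(table.n2, m)
    else:
        p_exact = min(1.0, 2 * _binom_tail(max(table.n2, table.n3), m))
    return McNemarResult(
        chi2_stat=float(chi2),
        p_chi2=p_chi2,
        p_exact=float(p_exact),
        rho=rho,
        reject=p_exact <= rho,
        alternative=alternative,
    )


def paired_t(p1, p2, alternative: str = "two_sided", rho: float = 0.05) -> PairedTResult:
    """Paired t-test on two equally long probability vectors.

    t = mean(delta) / (sd(delta) / sqrt(n)) with delta = p1 - p2 and
    df = n - 1 (sample sd, ddof = 1).  Alternatives: ``two_sided``,
    ``greater`` (delta > 0) or ``less`` (delta < 0).  A zero-variance
    delta with nonzero mean yields an infinite statistic flagged
    degenerate; an identically zero delta yields t = 0.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("paired_t needs two equal-length vectors, n >= 2")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    delta = a - b
    n = delta.size
    dbar = float(delta.mean())
    sd = float(delta.std(ddof=1))
    if sd == 0:
        if dbar == 0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, 0.0, n, alternative, degenerate=True)
        t = math.inf if dbar > 0 else -math.inf
        p = 0.0 if (
            alternative == "two_sided"
            or (alternative == "greater" and dbar > 0)
            or (alternative == "less" and dbar < 0)
        ) else 1.0
        return PairedTResult(t, n - 1, p, dbar, 0.0, n, alternative, degenerate=True)
    t = dbar / (sd / math.sqrt(n))
    if alternative == "two_sided":
        p = float(2 * sstats.t.sf(abs(t), df=n - 1))
    elif alternative == "greater":
        p = float(sstats.t.sf(t, df=n - 1))
    else:
        p = float(sstats.t.cdf(t, df=n - 1))
    return PairedTResult(float(t), n - 1, p, dbar, sd, n, alternative)


@dataclass
class BatteryConfig:
    """Regions, significance levels and grids for the six-test battery."""

    global_region: tuple[float, float] = (0.3, 1.0)
    transitional_region: tuple[float, float] = (0.3, 0.65)
    high_region: tuple[float, float] = (0.65, 1.0)
    rho_mcnemar: float = 0.01
    rho_high_region: float = 0.1
    rho_t: float = 0.05
    t_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 9.0, 1.0))
    filter_n: float = 0.0


def _exceedance_vector(
    pairs: pd.DataFrame, region: tuple[float, float], measure: str, grid: np.ndarray
) -> np.ndarray:
    """Observed P(measure >= mu + n*sigma | c in region) over the grid."""
    stats = region_stats(pairs, region)
    sub = filter_chemical_window(pairs, *region)
    v = sub[measure].to_numpy(dtype=float)
    mu = stats.mu_s if measure == "s" else stats.mu_d
    sigma = stats.sigma_s if measure == "s" else stats.sigma_d
    return np.array([(v >= mu + n * sigma).mean() for n in np.asarray(grid, dtype=float)])


def run_battery(pairs: pd.DataFrame, config: BatteryConfig | None = None) -> list[dict]:
    """Run the six-test comparison battery; returns one report dict per test.

    Each entry carries the test id, region(s), criterion description,
    the two compared proportions p1 (s side) and p2 (d side), the
    statistic, p-value, significance level and decision.  A region too
    sparse to test is reported as not computable and the battery
    continues.  No multiplicity correction is applied: the comparisons
    are designed as a coherent family, each read on its own terms.
    """
    cfg = config or BatteryConfig()
    results: list[dict] = []

    mcnemar_specs = [
        (1, cfg.global_region, cfg.rho_mcnemar),
        (2, cfg.transitional_region, cfg.rho_mcnemar),
        (3, cfg.high_region, cfg.rho_high_region),
    ]
    for test_id, region, rho in mcnemar_specs:
        entry = {
            "test_id": test_id,
            "kind": "mcnemar",
            "regions": [list(region)],
            "criterion": "s >= mu_s vs d >= mu_d",
        }
        try:
            table = build_contingency(pairs, region)
            res = mcnemar(table, rho=rho, alternative="n3_greater")
            entry.update(
                p1=table.p_first, p2=table.p_second,
                statistic=res.chi2_stat, p_value=res.p_exact, rho=rho,
                decision="reject_H0" if res.reject else "retain_H0",
            )
        except (DegenerateRegionError, InsufficientDataError) as exc:
            entry.update(decision="not_computable", reason=str(exc))
        results.append(entry)

    for test_id, measure in ((4, "s"), (5, "d")):
        entry = {
            "test_id": test_id,
            "kind": "paired_t",
            "regions": [list(cfg.transitional_region), list(cfg.high_region)],
            "criterion": f"{measure} exceedance across regions",
        }
        try:
            v1 = _exceedance_vector(pairs, cfg.transitional_region, measure, cfg.t_grid)
            v2 = _exceedance_vector(pairs, cfg.high_region, measure, cfg.t_grid)
            res = paired_t(v1, v2, alternative="greater", rho=cfg.rho_t)
            entry.update(
                p1=float(v1.mean()), p2=float(v2.mean()),
                statistic=res.t_stat, p_value=res.p, rho=cfg.rho_t,
                decision="reject_H0" if res.p <= cfg.rho_t else "retain_H0",
            )
        except (DegenerateRegionError, InsufficientDataError) as exc:
            entry.update(decision="not_computable", reason=str(exc))
        results.append(entry)

    entry = {
        "test_id": 6,
        "kind": "mcnemar",
        "regions": [list(cfg.high_region)],
        "criterion": "s <= mu_s - n*sigma_s vs d >= mu_d + n*sigma_d",
        "n": cfg.filter_n,
    }
    try:
        table = build_contingency(
            pairs, cfg.high_region, s_condition="below", d_condition="above",
            n_s=cfg.filter_n, n_d=cfg.filter_n,
        )
        res = mcnemar(table, rho=cfg.rho_mcnemar, alternative="n2_greater")
        entry.update(
            p1=table.p_first, p2=table.p_second,
            statistic=res.chi2_stat, p_value=res.p_exact, rho=cfg.rho_mcnemar,
            decision="reject_H0" if res.reject else "retain_H0",
        )
    except (DegenerateRegionError, InsufficientDataError) as exc:
        entry.update(decision="not_computable", reason=str(exc))
    results.append(entry)
    return results
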