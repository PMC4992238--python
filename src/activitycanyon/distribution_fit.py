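"""Marginal-distribution fitting for the pair weights.

Chemical similarity ``c`` and activity similarity ``s`` are modelled as
power laws, activity variation ``d`` as an exponential.  All exponents
are estimated the same way the empirical curves are read off a log-log
or semilog plot: ordinary least squares on the log-transformed relative
frequencies.  Support points with zero observed probability are dropped
before the log transform.

A maximum-likelihood alternative is available for cross-checks
(:func:`fit_power_law_mle`), but OLS on log frequencies is the reference
estimator throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from activitycanyon.errors import InsufficientDataError

DEFAULT_C_BIN_WIDTH = 0.01


@dataclass
class EmpiricalDistribution:
    """Relative-frequency distribution over an observed support.

    Integer-valued measures (s, d) use exact-value support; continuous
    measures (c) use fixed-width bins starting at the sample minimum,
    with bin midpoints as support.
    """

    support: np.ndarray
    probability: np.ndarray
    n_total: int
    bin_width: float | None = None

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        """Support and probability restricted to nonzero-probability points."""
        mask = self.probability > 0
        return self.support[mask], self.probability[mask]


@dataclass
class PowerLawFit:
    """OLS fit of log(p) = -exponent * log(x) + intercept.

    The reported ``exponent`` is positive (the sign-flipped slope);
    ``stderr`` is the OLS standard error of the slope.
    """

    exponent: float
    intercept: float
    x_min: float
    stderr: float
    fit_range: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_range"] = list(self.fit_range)
        return d


@dataclass
class ExponentialFit:
    """OLS fit of log(p) = -rate * x + intercept; ``rate`` is positive."""

    rate: float
    intercept: float
    d_min: float
    stderr: float
    fit_range: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_range"] = list(self.fit_range)
        return d


def empirical_pmf(values, bin_width: float | None = None) -> EmpiricalDistribution:
    """Relative frequencies of observed values.

    With ``bin_width`` set, values are histogrammed in fixed-width bins
    starting at the minimum and the support holds bin midpoints.
    Without it, values must be (near-)integers and the support is the
    sorted set of distinct observed values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("empirical_pmf: empty input")
    n = vals.size
    if bin_width is not None:
        lo = vals.min()
        n_bins = max(1, int(np.ceil((vals.max() - lo) / bin_width - 1e-12)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(vals, bins=edges)
        mids = edges[:-1] + bin_width / 2
        return EmpiricalDistribution(mids, counts / n, n, bin_width)
    support, counts = np.unique(vals, return_counts=True)
    return EmpiricalDistribution(support, counts / n, n, None)


def _fit_points(
    dist: EmpiricalDistribution,
    fit_range: tuple[float, float] | None,
    positive_support: bool,
) -> tuple[np.ndarray, np.ndarray]:
    x, p = dist.nonzero()
    if positive_support:
        keep = x > 0
        x, p = x[keep], p[keep]
    if fit_range is not None:
        lo, hi = fit_range
        keep = (x >= lo) & (x <= hi)
        x, p = x[keep], p[keep]
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 usable support points, got {x.size}"
        )
    return x, p


def fit_power_law(
    dist: EmpiricalDistribution, fit_range: tuple[float, float] | None = None
) -> PowerLawFit:
    """Power-law exponent by OLS of log(probability) on log(value).

    ``fit_range`` restricts the regression to support points in
    ``[lo, hi]``; by default every positive support point with nonzero
    probability is used.  The returned exponent is the negated slope.
    """
    x, p = _fit_points(dist, fit_range, positive_support=True)
    res = stats.linregress(np.log(x), np.log(p))
    lo, hi = (float(x.min()), float(x.max())) if fit_range is None else fit_range
    return PowerLawFit(
        exponent=-res.slope,
        intercept=res.intercept,
        x_min=float(x.min()),
        stderr=res.stderr,
        fit_range=(lo, hi),
        n_points=int(x.size),
    )


def fit_exponential(
    dist: EmpiricalDistribution, fit_range: tuple[float, float] | None = None
) -> ExponentialFit:
    """Exponential decay rate by OLS of log(probability) on value.

    The semilog slope is invariant to shifting the support, so the fitted
    rate does not depend on the minimum value ``d_min``.
    """
    x, p = _fit_points(dist, fit_range, positive_support=False)
    res = stats.linregress(x, np.log(p))
    lo, hi = (float(x.min()), float(x.max())) if fit_range is None else fit_range
    return ExponentialFit(
        rate=-res.slope,
        intercept=res.intercept,
        d_min=float(x.min()),
        stderr=res.stderr,
        fit_range=(lo, hi),
        n_points=int(x.size),
    )


def reliable_range(dist: EmpiricalDistribution, min_count: int = 10) -> tuple[float, float]:
    """Largest contiguous-from-the-left support range with counts >= min_count.

    Sparse tail points (a handful of observations each) flatten log-scale
    regressions; restricting the fit to well-populated support is the
    standard remedy when no external fit range is prescribed.
    """
    counts = dist.probability * dist.n_total
    ok = counts >= min_count
    if not ok.any():
        raise InsufficientDataError("no support point reaches the requested count")
    # stop at the first under-populated point past the first populated one
    start = int(np.argmax(ok))
    end = start
    for i in range(start, ok.size):
        if ok[i]:
            end = i
        else:
            break
    return float(dist.support[start]), float(dist.support[end])


def fit_power_law_mle(values, x_min: float) -> float:
    """Continuous-MLE (Hill) exponent estimate, for cross-checking OLS fits.

    alpha_hat = 1 + n / sum(log(x / x_min)) over values >= x_min.
    """
    x = np.asarray(values, dtype=float)
    x = x[x >= x_min]
    if x.size < 2:
        raise InsufficientDataError("too few values above x_min for MLE")
    return 1.0 + x.size / np.sum(np.log(x / x_min))
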