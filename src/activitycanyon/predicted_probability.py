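"""Closed-form predicted probabilities under structure-activity independence.

The marginals are a power law for chemical similarity ``c`` (exponent
gamma, minimum c_min), a power law for activity similarity ``s``
(exponent alpha, minimum s_min) and an exponential for activity
variation ``d`` (rate lambda, minimum d_min).  Assuming structure and
activity are generated independently, the joint probability of a
rectangular range factorizes into the product of the two marginal range
integrals, each with an elementary antiderivative:

    P(c1 <= c <= c2  and  s1 <= s <= s2)
        = c_min^(gamma-1) (c1^(1-gamma) - c2^(1-gamma))
          * s_min^(alpha-1) (s1^(1-alpha) - s2^(1-alpha))

    P(c1 <= c <= c2  and  d1 <= d <= d2)
        = c_min^(gamma-1) (c1^(1-gamma) - c2^(1-gamma))
          * K_d (exp(-lambda d1) - exp(-lambda d2))

Two evaluation modes are provided.  ``normalized`` uses properly
normalized densities on each axis (K_d = exp(lambda*d_min), so the
full-range probability is 1 per axis).  ``paper_constants`` keeps the
historical regression prefactor for the d axis, K_d = (k_d / lambda) *
exp(lambda*d_min) with k_d = 0.042 by default; the published closed form
for the (c, s) joint coincides with the normalized power-law integral,
so the s-axis prefactor k_s is recorded for reference but does not enter
either mode.  Predicted curves are compared against observations only up
to an overall scale, so the mode affects reported magnitudes, not fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from activitycanyon.distinctiveness import RegionStats, region_stats
from activitycanyon.errors import (
    DegenerateRegionError,
    InsufficientDataError,
    OutOfSupportError,
)
from activitycanyon.pair_network import filter_chemical_window

DEFAULT_N_GRID = np.round(np.arange(0.0, 9.0 + 1e-9, 0.2), 10)


@dataclass
class ModelConstants:
    """Fitted marginal-distribution parameters of the landscape model.

    Defaults are the constants estimated on the original drug ensemble:
    gamma = 3.6 (c power law), alpha = 2.37 (s power law), lambda = 0.17
    (d exponential), with support minima c_min = 0.004, s_min = 1,
    d_min = 0 and regression prefactors k_s = 0.045, k_d = 0.042.
    """

    alpha: float = 2.37
    gamma: float = 3.6
    lambda_: float = 0.17
    s_min: float = 1.0
    c_min: float = 0.004
    d_min: float = 0.0
    k_s: float = 0.045
    k_d: float = 0.042
    mode: str = "normalized"

    def __post_init__(self) -> None:
        if self.mode not in ("normalized", "paper_constants"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.alpha <= 1 or self.gamma <= 1:
            raise ValueError("power-law exponents must exceed 1 for finite tail mass")
        if self.lambda_ <= 0:
            raise ValueError("exponential rate must be positive")
        if self.s_min <= 0 or self.c_min <= 0:
            raise ValueError("power-law minima must be positive")

    # -- marginal densities (used by quadrature cross-checks) ---------------

    def pdf_c(self, c: float) -> float:
        """Normalized power-law density of c on [c_min, inf)."""
        if c < self.c_min:
            return 0.0
        return (self.gamma - 1) / self.c_min * (c / self.c_min) ** (-self.gamma)

    def pdf_s(self, s: float) -> float:
        """Power-law density of s on [s_min, inf).

        The closed-form (c, s) joint integrates the normalized density in
        both modes, so this does not depend on ``mode``.
        """
        if s < self.s_min:
            return 0.0
        return (self.alpha - 1) / self.s_min * (s / self.s_min) ** (-self.alpha)

    def pdf_d(self, d: float) -> float:
        """Exponential density of d on [d_min, inf); mode-dependent prefactor."""
        if d < self.d_min:
            return 0.0
        if self.mode == "paper_constants":
            return self.k_d * math.exp(self.lambda_ * self.d_min) * math.exp(-self.lambda_ * d)
        return self.lambda_ * math.exp(-self.lambda_ * (d - self.d_min))

    # -- marginal range integrals -------------------------------------------

    def prob_c_range(self, c1: float, c2: float) -> float:
        if c1 < self.c_min - 1e-12:
            raise OutOfSupportError(f"c1 = {c1} below c_min = {self.c_min}")
        if c2 < c1:
            raise ValueError("c2 < c1")
        g = self.gamma
        upper = 0.0 if math.isinf(c2) else c2 ** (1 - g)
        return self.c_min ** (g - 1) * (c1 ** (1 - g) - upper)

    def prob_s_range(self, s1: float, s2: float) -> float:
        if s1 < self.s_min - 1e-12:
            raise OutOfSupportError(f"s1 = {s1} below s_min = {self.s_min}")
        if s2 < s1:
            raise ValueError("s2 < s1")
        a = self.alpha
        upper = 0.0 if math.isinf(s2) else s2 ** (1 - a)
        return self.s_min ** (a - 1) * (s1 ** (1 - a) - upper)

    def prob_d_range(self, d1: float, d2: float) -> float:
        if d1 < self.d_min - 1e-12:
            raise OutOfSupportError(f"d1 = {d1} below d_min = {self.d_min}")
        if d2 < d1:
            raise ValueError("d2 < d1")
        lam = self.lambda_
        upper = 0.0 if math.isinf(d2) else math.exp(-lam * d2)
        core = math.exp(-lam * d1) - upper
        if self.mode == "paper_constants":
            return (self.k_d / lam) * math.exp(lam * self.d_min) * core
        return math.exp(lam * self.d_min) * core


@dataclass
class RangeQuery:
    """Rectangular query: a c window crossed with an s or d window.

    Upper bounds may be ``math.inf``; the limit terms are evaluated
    analytically.
    """

    c1: float
    c2: float
    lo: float
    hi: float
    measure: str  # "s" or "d"

    def __post_init__(self) -> None:
        if self.measure not in ("s", "d"):
            raise ValueError(f"measure must be 's' or 'd', got {self.measure!r}")
        if self.c2 < self.c1 or self.hi < self.lo:
            raise ValueError("upper bound below lower bound")


def predicted_prob_cs(k: ModelConstants, q: RangeQuery) -> float:
    """Predicted probability of (c, s) falling in the query rectangle."""
    if q.measure != "s":
        raise ValueError("predicted_prob_cs requires an s-measure query")
    return k.prob_c_range(q.c1, q.c2) * k.prob_s_range(q.lo, q.hi)


def predicted_prob_cd(k: ModelConstants, q: RangeQuery) -> float:
    """Predicted probability of (c, d) falling in the query rectangle."""
    if q.measure != "d":
        raise ValueError("predicted_prob_cd requires a d-measure query")
    return k.prob_c_range(q.c1, q.c2) * k.prob_d_range(q.lo, q.hi)


def predicted_prob(k: ModelConstants, q: RangeQuery) -> float:
    """Dispatch on the query's measure."""
    return predicted_prob_cs(k, q) if q.measure == "s" else predicted_prob_cd(k, q)


def observed_prob(pairs: pd.DataFrame, q: RangeQuery, conditional_on_c: bool = False) -> float:
    """Observed probability of the query rectangle in the pair table.

    Joint mode divides by all pairs; conditional mode divides by the
    pairs inside the c window only (the convention P(c) = 1 within a
    fixed chemical range).  All bounds are inclusive.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("observed_prob: empty pair table")
    c = pairs["c"].to_numpy(dtype=float)
    v = pairs[q.measure].to_numpy(dtype=float)
    in_c = (c >= q.c1) & (c <= q.c2)
    in_v = (v >= q.lo) & (v <= q.hi)
    denom = int(in_c.sum()) if conditional_on_c else len(pairs)
    if denom == 0:
        raise DegenerateRegionError(f"no pairs with c in [{q.c1}, {q.c2}]")
    return float((in_c & in_v).sum() / denom)


def rmse(p_pred, p_obs) -> float:
    """Root mean square error with the (J - 1) denominator convention."""
    a = np.asarray(p_pred, dtype=float)
    b = np.asarray(p_obs, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction and observation vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 points for RMSE")
    return float(np.sqrt(np.sum((a - b) ** 2) / (a.size - 1)))


def scale_predictions(p_pred, p_obs) -> tuple[np.ndarray, float]:
    """Least-squares scalar match of predictions to observations.

    Returns (scaled predictions, factor) with
    factor = sum(pred * obs) / sum(pred^2), the minimizer of
    ||factor * pred - obs||^2.
    """
    a = np.asarray(p_pred, dtype=float)
    b = np.asarray(p_obs, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction and observation vectors differ in length")
    denom = float(np.sum(a * a))
    if denom == 0:
        raise ValueError("cannot scale an all-zero prediction vector")
    factor = float(np.sum(a * b) / denom)
    return a * factor, factor


@dataclass
class ProbabilityScan:
    """Observed vs predicted exceedance probabilities over an n-sigma grid."""

    measure: str
    region: tuple[float, float]
    stats: RegionStats
    n_grid: np.ndarray
    thresholds: np.ndarray
    p_obs: np.ndarray
    p_pred: np.ndarray
    p_pred_scaled: np.ndarray = field(repr=False)
    scale_factor: float = 1.0
    rmse: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n_grid,
                "threshold": self.thresholds,
                "p_obs": self.p_obs,
                "p_pred_raw": self.p_pred,
                "p_pred_scaled": self.p_pred_scaled,
            }
        )


def scan_thresholds(
    pairs: pd.DataFrame,
    k: ModelConstants,
    region: tuple[float, float] = (0.3, 1.0),
    n_grid=DEFAULT_N_GRID,
    measure: str = "d",
    conditional_on_c: bool = True,
) -> ProbabilityScan:
    """Scan mean-plus-n-sigma exceedance thresholds within a chemical region.

    For each multiplier n the threshold is mu + n*sigma of the measure
    over pairs in the region (clamped to the model's support minimum),
    the observed probability is the fraction of region pairs at or above
    the threshold, and the prediction is the closed-form joint
    probability of the region crossed with [threshold, inf).  Predictions
    are least-squares scaled to the observations and the RMSE of the
    scaled curve is attached.
    """
    if measure not in ("s", "d"):
        raise ValueError(f"measure must be 's' or 'd', got {measure!r}")
    stats = region_stats(pairs, region)
    sub = filter_chemical_window(pairs, *region)
    values = sub[measure].to_numpy(dtype=float)
    mu = stats.mu_s if measure == "s" else stats.mu_d
    sigma = stats.sigma_s if measure == "s" else stats.sigma_d
    support_min = k.s_min if measure == "s" else k.d_min

    n_grid = np.asarray(n_grid, dtype=float)
    thresholds = np.maximum(mu + n_grid * sigma, support_min)
    p_obs = np.array([(values >= t).mean() for t in thresholds])
    if not conditional_on_c:
        p_obs = p_obs * len(sub) / len(pairs)
    p_pred = np.array(
        [
            predicted_prob(
                k, RangeQuery(region[0], region[1], float(t), math.inf, measure)
            )
            for t in thresholds
        ]
    )
    p_scaled, factor = scale_predictions(p_pred, p_obs)
    err = rmse(p_scaled, p_obs) if p_scaled.size >= 2 else float("nan")
    return ProbabilityScan(
        measure=measure,
        region=(float(region[0]), float(region[1])),
        stats=stats,
        n_grid=n_grid,
        thresholds=thresholds,
        p_obs=p_obs,
        p_pred=p_pred,
        p_pred_scaled=p_scaled,
        scale_factor=factor,
        rmse=err,
    )
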