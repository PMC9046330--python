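"""Fit sampling distributions to a published mean and 95% confidence interval.

Probabilistic sensitivity analysis needs a full distribution for every
uncertain input, but published sources print only a point estimate and a
95% CI.  The standard practice is a method-of-moments fit with the
normal-approximation standard error SE = (ci_high - ci_low) / 3.92:

* probabilities and utilities  -> Beta(alpha, beta)
* costs                        -> Gamma(shape, scale)
* relative risks               -> logNormal(mu, sigma), the printed RR
  treated as the median because ratio estimates are pooled on the log
  scale.

Each fit is exact in its matched moment: the beta and gamma fits
reproduce the input mean analytically, the lognormal fit reproduces the
input RR as its median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import InfeasibleVarianceError

#: width of a 95% normal interval in standard errors (2 x 1.96)
CI_WIDTH_SE = 3.92


def _se_from_ci(ci_low: float, ci_high: float) -> float:
    if not ci_high > ci_low:
        raise ValueError(f"ci_high ({ci_high}) must exceed ci_low ({ci_low})")
    return (ci_high - ci_low) / CI_WIDTH_SE


def fit_beta_from_ci(mean: float, ci_low: float, ci_high: float) -> Tuple[float, float]:
    """Method-of-moments Beta fit; returns ``(alpha, beta)``.

    alpha + beta = mean(1-mean)/SE^2 - 1 and alpha = mean * (alpha+beta).
    Raises :class:`InfeasibleVarianceError` when SE^2 >= mean(1-mean),
    where no beta distribution has the requested moments.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta fit needs mean in (0, 1), got {mean}")
    se = _se_from_ci(ci_low, ci_high)
    var = se * se
    if var >= mean * (1.0 - mean):
        raise InfeasibleVarianceError(
            f"variance {var:g} >= mean(1-mean) = {mean * (1 - mean):g}; "
            "no beta distribution matches"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_from_ci(mean: float, ci_low: float, ci_high: float) -> Tuple[float, float]:
    """Method-of-moments Gamma fit; returns ``(shape, scale)``.

    shape = mean^2/SE^2, scale = SE^2/mean, so shape*scale == mean.
    """
    if not mean > 0.0:
        raise ValueError(f"gamma fit needs positive mean, got {mean}")
    se = _se_from_ci(ci_low, ci_high)
    var = se * se
    return mean * mean / var, var / mean


def fit_lognormal_from_ci(rr: float, ci_low: float, ci_high: float) -> Tuple[float, float]:
    """Lognormal fit for a relative risk; returns ``(mu, sigma)``.

    The printed RR is the median: mu = ln(rr); sigma is read off the CI
    on the log scale, sigma = (ln ci_high - ln ci_low) / 3.92.  A point
    estimate with a degenerate CI (lo == rr == hi) yields sigma = 0.
    """
    if not (ci_low > 0.0 and rr > 0.0 and ci_high > 0.0):
        raise ValueError("lognormal fit needs strictly positive rr and CI bounds")
    if not ci_low <= rr <= ci_high:
        raise ValueError(f"rr {rr} outside its CI ({ci_low}, {ci_high})")
    sigma = (math.log(ci_high) - math.log(ci_low)) / CI_WIDTH_SE
    return math.log(rr), sigma


@dataclass(frozen=True)
class FittedDistribution:
    """A ready-to-sample distribution for one uncertain parameter."""

    family: str  # "beta" | "gamma" | "lognormal" | "fixed"
    a: float  # alpha / shape / mu / fixed value
    b: float  # beta / scale / sigma / 0

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size)
        if self.family == "lognormal":
            if self.b == 0.0:
                return np.broadcast_to(math.exp(self.a), () if size is None else (size,)).copy()
            return rng.lognormal(self.a, self.b, size)
        if self.family == "fixed":
            return np.broadcast_to(self.a, () if size is None else (size,)).copy()
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def central_value(self) -> float:
        """Analytic mean (beta/gamma), median (lognormal) or the fixed value."""
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        if self.family == "lognormal":
            return math.exp(self.a)
        return self.a


def fit_distribution(
    family: str, mean: float, ci_low: float, ci_high: float
) -> FittedDistribution:
    """Dispatch a CI-based fit by distribution family."""
    if family == "fixed" or ci_low == ci_high:
        return FittedDistribution("fixed", mean, 0.0)
    if family == "beta":
        a, b = fit_beta_from_ci(mean, ci_low, ci_high)
        return FittedDistribution("beta", a, b)
    if family == "gamma":
        a, b = fit_gamma_from_ci(mean, ci_low, ci_high)
        return FittedDistribution("gamma", a, b)
    if family == "lognormal":
        a, b = fit_lognormal_from_ci(mean, ci_low, ci_high)
        return FittedDistribution("lognormal", a, b)
    raise ValueError(f"unknown distribution family {family!r}")
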