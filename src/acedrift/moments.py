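"""Closed-form moments of the accumulated copying error (ACE) model.

The ACE model describes the cultural transmission of a continuous artifact
attribute (here: size in cm) along a chain of individuals, each of whom
copies the previous individual's artifact as faithfully as possible.
Because perceptual error obeys Weber's law — error is proportional to the
magnitude of the perceived attribute — copying error enters
multiplicatively:

    X_t = X_{t-1} * eps_t,    eps_t ~ i.i.d. Normal(1, sigma^2)

with X_0 = x0 the seed size.  From E[eps] = 1 and E[eps^2] = 1 + sigma^2 it
follows that

    E[X_t]   = x0                                  (mean conserved)
    Var[X_t] = x0^2 * ((1 + sigma^2)^t - 1)        (exponential growth)

so independently evolving chains keep a constant expected size while the
between-chain variance grows without bound, at rate log(1 + sigma^2) per
generation.

A normal error ratio can in principle be non-positive.
:func:`truncated_error_moments` quantifies how little truncating the error
distribution below at zero changes its mean and sd at empirically realistic
sigma (a few percent): the truncation point sits tens of standard
deviations below the mean, so the difference is negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from numbers import Integral

import numpy as np
from scipy import stats as sps

__all__ = [
    "ErrorModel",
    "MomentPrediction",
    "expected_mean",
    "expected_variance",
    "moment_prediction",
    "truncated_error_moments",
]


@dataclass(frozen=True)
class ErrorModel:
    """Distribution of a single copying-error ratio eps.

    Parameters
    ----------
    mu:
        Mean of the error ratio. The ACE model fixes this at 1 (unbiased
        copying); synthetic bias experiments may override it.
    sigma:
        Standard deviation of the error ratio (dimensionless). The Weber
        fraction for line length (~3%) motivates values near 0.03.
    truncated:
        Whether the distribution is truncated below at 0 so that error
        ratios are strictly positive.
    """

    mu: float = 1.0
    sigma: float = 0.0343
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class MomentPrediction:
    """Predicted mean and variance trajectories of a single chain.

    ``mean_traj[t]`` and ``var_traj[t]`` are the model's E[X_t] (cm) and
    Var[X_t] (cm^2) for t = 0..T.
    """

    x0: float
    sigma: float
    T: int
    mean_traj: np.ndarray = field(repr=False)
    var_traj: np.ndarray = field(repr=False)


def _check_args(x0: float, sigma: float, t) -> int:
    if x0 <= 0:
        raise ValueError(f"x0 must be > 0, got {x0}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if isinstance(t, bool) or not isinstance(t, Integral):
        raise ValueError(f"t must be an integer generation count, got {t!r}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return int(t)


def expected_mean(x0: float, sigma: float, t: int) -> float:
    """E[X_t] for a single ACE chain: always the starting value x0.

    The error ratios have mean 1 and are independent of the current size,
    so the expectation is conserved for every horizon t.
    """
    _check_args(x0, sigma, t)
    return float(x0)


def expected_variance(x0: float, sigma: float, t: int) -> float:
    """Var[X_t] = x0^2 * ((1 + sigma^2)^t - 1).

    Zero at t = 0, strictly increasing and unbounded for sigma > 0, with
    exponential growth rate log(1 + sigma^2).  For extreme t the power may
    overflow; the result is then ``inf`` with a warning rather than a
    silently saturated value.
    """
    t = _check_args(x0, sigma, t)
    with np.errstate(over="ignore"):
        growth = np.power(1.0 + sigma**2, t)
    if np.isinf(growth):
        warnings.warn(
            f"(1+sigma^2)^t overflowed at t={t}; returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(x0**2 * (growth - 1.0))


def moment_prediction(x0: float, sigma: float, T: int) -> MomentPrediction:
    """Mean and variance trajectories for t = 0..T (both length T+1)."""
    T = _check_args(x0, sigma, T)
    t = np.arange(T + 1)
    mean_traj = np.full(T + 1, float(x0))
    with np.errstate(over="ignore"):
        var_traj = x0**2 * (np.power(1.0 + sigma**2, t) - 1.0)
    if np.isinf(var_traj).any():
        warnings.warn("variance trajectory overflowed to inf", RuntimeWarning, stacklevel=2)
    return MomentPrediction(x0=float(x0), sigma=float(sigma), T=T,
                            mean_traj=mean_traj, var_traj=var_traj)


def truncated_error_moments(sigma: float) -> tuple[float, float]:
    """Mean and sd of Normal(1, sigma^2) truncated below at 0.

    Diagnostic for the objection that a normal error ratio can be
    non-positive: at empirically realistic sigma the truncation point lies
    1/sigma standard deviations below the mean, so the truncated moments
    are indistinguishable from (1, sigma) in double precision.  The
    distribution itself comes from :mod:`scipy.stats`' truncated normal.

    Returns
    -------
    (mean, sd) of the truncated distribution.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0 for a truncated error model, got {sigma}")
    a = (0.0 - 1.0) / sigma  # lower bound in standard units
    mean, var = sps.truncnorm.stats(a, np.inf, loc=1.0, scale=sigma, moments="mv")
    return float(mean), float(np.sqrt(var))
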