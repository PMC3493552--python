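"""Macroevolutionary calibration of the ACE model via the pooled CV.

Archaeological size variation is usually summarized as a coefficient of
variation over all artifacts of a class (e.g. 0.30 for handaxe length,
0.23 for breadth, over 2601 specimens).  The corresponding model summary
is the pooled CV of an ensemble of chains: sd/mean over every value
produced by every chain across all generations.  An analytic expression
for this quantity is intractable, so it is estimated by simulation of the
standard ensemble (100 chains, seed size 1, values pooled over all
generations), following the one-line procedure
``cv(c(replicate(100, cumprod(rnorm(T, 1, sigma)))))``.

Two inversions connect experiment and record:

* :func:`generations_to_cv` — given a measured copying-error sd sigma, how
  many generations until the pooled CV reaches an archaeological target?
* :func:`sigma_for_cv` — given a time depth in generations, what sigma
  would produce the observed CV?  (Monotone bisection on the simulated
  median CV.)

A single simulated ensemble is a lottery ticket; both solvers therefore
work on the MEDIAN pooled CV over a set of independently seeded replicate
ensembles (default 25) and report the replicate spread.  Common random
numbers across sigma values keep the bisection objective deterministic
and monotone.  Generations convert to calendar time at 20 years per
generation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import brentq

from .errors import NumericFailure

__all__ = [
    "CalibrationResult",
    "generations_to_cv",
    "sigma_for_cv",
    "generations_to_years",
    "DEFAULT_GENERATION_YEARS",
]

#: ethnographically conventional human generation time
DEFAULT_GENERATION_YEARS = 20.0


@dataclass
class CalibrationResult:
    """Outcome of a CV calibration run.

    ``solved_value`` is a generation count (:func:`generations_to_cv`) or
    a copying-error sd (:func:`sigma_for_cv`); ``fixed_parameter`` names
    the quantity held fixed and its value.  ``reached`` is False when no
    horizon up to the supplied bound attains the target CV; the result is
    then a report, not an exception.
    """

    solved_value: float | None
    target_cv: float
    fixed_parameter: tuple[str, float]
    n_chains: int
    replicates: int
    seed: int
    cv_at_solution: float | None
    reached: bool = True
    spread: dict[str, float] = field(default_factory=dict)
    details: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "solved_value": self.solved_value,
            "target_cv": self.target_cv,
            "fixed_parameter": {self.fixed_parameter[0]: self.fixed_parameter[1]},
            "n_chains": self.n_chains,
            "replicates": self.replicates,
            "seed": self.seed,
            "cv_at_solution": self.cv_at_solution,
            "reached": self.reached,
            "spread": self.spread,
            "details": self.details,
        }


def _replicate_seeds(seed: int, replicates: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(replicates)


def _chain_values(rng: np.random.Generator, sigma: float, n_chains: int,
                  T: int, standard_normal: np.ndarray | None = None) -> np.ndarray:
    """(n_chains, T) array of chain values (x0 = 1) for one replicate.

    If ``standard_normal`` is given, error ratios are 1 + sigma*z (common
    random numbers); non-positive ratios, impossible at calibration-scale
    sigma but possible at a wide bisection bracket, are resampled.
    """
    if standard_normal is None:
        eps = rng.normal(1.0, sigma, size=(n_chains, T))
    else:
        eps = 1.0 + sigma * standard_normal
    bad = eps <= 0.0
    while bad.any():
        eps[bad] = rng.normal(1.0, sigma, size=int(bad.sum()))
        bad = eps <= 0.0
    return np.cumprod(eps, axis=1)


def _cv_curve(values: np.ndarray) -> np.ndarray:
    """Pooled CV at every horizon t = 1..T from one replicate's values.

    ``values[c, t-1]`` is chain c at generation t; the pooled set at
    horizon t is all entries of the first t columns.  Cumulative sums of
    values and squares give every horizon in one pass.
    """
    n_chains, T = values.shape
    s1 = np.cumsum(values.sum(axis=0))
    s2 = np.cumsum((values**2).sum(axis=0))
    n = n_chains * np.arange(1, T + 1)
    mean = s1 / n
    var = np.full(T, np.nan)
    ok = n > 1
    var[ok] = (s2[ok] - n[ok] * mean[ok] ** 2) / (n[ok] - 1)
    var = np.clip(var, 0.0, None)
    return np.sqrt(var) / mean


def generations_to_cv(sigma: float, cv_target: float, n_chains: int = 100,
                      replicates: int = 25, seed: int = 0, max_T: int = 400,
                      ) -> CalibrationResult:
    """Smallest horizon at which the median pooled CV reaches ``cv_target``.

    Simulates ``replicates`` independent ensembles of ``n_chains`` chains
    for ``max_T`` generations (seed size 1), computes each replicate's
    pooled-CV curve over horizons 1..max_T, takes the across-replicate
    median curve, and returns the first horizon at which it reaches the
    target.  If the target is never reached the result has
    ``reached=False`` and ``solved_value=None``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if cv_target <= 0:
        raise ValueError(f"cv_target must be > 0, got {cv_target}")
    if max_T < 1:
        raise ValueError(f"max_T must be >= 1, got {max_T}")

    curves = np.empty((replicates, max_T))
    crossings: list[int | None] = []
    for i, child in enumerate(_replicate_seeds(seed, replicates)):
        rng = np.random.default_rng(child)
        if sigma == 0:
            curves[i] = 0.0
        else:
            curves[i] = _cv_curve(_chain_values(rng, sigma, n_chains, max_T))
        hit = np.flatnonzero(curves[i] >= cv_target)
        crossings.append(int(hit[0]) + 1 if hit.size else None)

    median_curve = np.median(curves, axis=0)
    hit = np.flatnonzero(median_curve >= cv_target)
    fixed = ("sigma", float(sigma))
    if hit.size == 0:
        return CalibrationResult(
            solved_value=None, target_cv=cv_target, fixed_parameter=fixed,
            n_chains=n_chains, replicates=replicates, seed=seed,
            cv_at_solution=float(median_curve[-1]), reached=False,
            spread=_spread(curves[:, -1]),
            details={"max_T": max_T, "replicate_crossings": crossings})
    t_star = int(hit[0]) + 1  # horizons are 1-based
    return CalibrationResult(
        solved_value=t_star, target_cv=cv_target, fixed_parameter=fixed,
        n_chains=n_chains, replicates=replicates, seed=seed,
        cv_at_solution=float(median_curve[t_star - 1]), reached=True,
        spread=_spread(curves[:, t_star - 1]),
        details={"max_T": max_T, "replicate_crossings": crossings})


def _spread(values: np.ndarray) -> dict[str, float]:
    return {
        "min": float(np.min(values)),
        "q25": float(np.quantile(values, 0.25)),
        "q75": float(np.quantile(values, 0.75)),
        "max": float(np.max(values)),
    }


def _median_pooled_cv(sigma: float, T: int, n_chains: int,
                      seeds: list[np.random.SeedSequence]) -> tuple[float, np.ndarray]:
    """Median (and per-replicate values) of the pooled CV at horizon T."""
    cvs = np.empty(len(seeds))
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        z = rng.standard_normal((n_chains, T))
        values = _chain_values(rng, sigma, n_chains, T, standard_normal=z).ravel()
        cvs[i] = values.std(ddof=1) / values.mean()
    return float(np.median(cvs)), cvs


def _sigma_initial_guess(T: int, cv_target: float) -> float:
    """Continuous-time approximation: pooled Var ~ (e^g - 1)/g - 1, g = sigma^2 T."""
    target = cv_target**2

    def h(g: float) -> float:
        return float(np.expm1(g) / g - 1.0 - target)

    try:
        g = brentq(h, 1e-12, 60.0)
    except ValueError:
        g = 2.0 * target
    return float(np.sqrt(g / T))


def sigma_for_cv(T: int, cv_target: float, n_chains: int = 100,
                 replicates: int = 25, seed: int = 0, rtol: float = 0.02,
                 max_iter: int = 60) -> CalibrationResult:
    """Copying-error sd whose median pooled CV at horizon T hits the target.

    The objective — the median over replicates of the pooled CV of
    ``n_chains`` chains after ``T`` generations — is evaluated with common
    random numbers (each replicate's standard-normal draws are fixed by
    its child seed), which makes it a deterministic, monotone function of
    sigma.  Geometric bisection refines sigma until the objective is
    within relative tolerance ``rtol`` of ``cv_target``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if cv_target <= 0:
        raise ValueError(f"cv_target must be > 0, got {cv_target}")

    seeds = _replicate_seeds(seed, replicates)

    def f(s: float) -> float:
        return _median_pooled_cv(s, T, n_chains, seeds)[0]

    sigma0 = _sigma_initial_guess(T, cv_target)
    lo, hi = sigma0 / 4.0, min(sigma0 * 4.0, 2.0)
    f_lo, f_hi = f(lo), f(hi)
    for _ in range(10):
        if f_lo <= cv_target:
            break
        lo /= 4.0
        f_lo = f(lo)
    for _ in range(10):
        if f_hi >= cv_target or hi >= 2.0:
            break
        hi = min(hi * 4.0, 2.0)
        f_hi = f(hi)
    if not (f_lo <= cv_target <= f_hi):
        raise NumericFailure(
            f"cannot bracket CV target {cv_target}: achievable CV range at "
            f"T={T} over sigma in [{lo:.3g}, {hi:.3g}] is [{f_lo:.4g}, {f_hi:.4g}]")

    mid, f_mid, iterations = lo, f_lo, 0
    for iterations in range(1, max_iter + 1):
        mid = float(np.sqrt(lo * hi))
        f_mid = f(mid)
        if abs(f_mid - cv_target) <= rtol * cv_target:
            break
        if f_mid < cv_target:
            lo = mid
        else:
            hi = mid
    else:
        raise NumericFailure(
            f"bisection did not reach |CV - {cv_target}| <= {rtol:.0%} in "
            f"{max_iter} iterations (last CV {f_mid:.4g})")

    _, cvs = _median_pooled_cv(mid, T, n_chains, seeds)
    return CalibrationResult(
        solved_value=float(mid), target_cv=cv_target,
        fixed_parameter=("T", float(T)), n_chains=n_chains,
        replicates=replicates, seed=seed, cv_at_solution=float(f_mid),
        reached=True, spread=_spread(cvs),
        details={"iterations": iterations, "rtol": rtol,
                 "initial_guess": sigma0})


def generations_to_years(T: float, generation_time: float = DEFAULT_GENERATION_YEARS
                         ) -> float:
    """Convert a generation count to calendar years (default 20 yr/gen)."""
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    return float(T) * float(generation_time)
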