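"""Statistical analysis of copying-error samples.

Three questions drive the analysis of a transmission-chain experiment:

1. What is the copying-error sd sigma?  Estimated as the sample standard
   deviation of the observed produced/target ratios, per condition or
   pooled.
2. Are the error ratios normal?  Tested with the Anderson-Darling
   statistic for the composite normal null (mean and variance estimated
   from the sample), using the small-sample correction
   A* = A^2 (1 + 0.75/n + 2.25/n^2) and the standard case-3 p-value
   approximation.
3. Do the chains end where the ACE model predicts?  The final cross-chain
   mean and sample variance are compared to the model by Monte-Carlo
   simulation of the experimental design: the empirical p-value is the
   proportion of simulated experiments whose final statistic is at least
   as extreme as the observed one, in one direction.

On the p-value direction: the default ("auto") fixes the direction from
the sign of observed - predicted, the natural choice when a single
experimental outcome is in hand.  Because either tail can then yield a
small p, the null rate of p < alpha is ~2*alpha; for calibration studies
where a uniform null p is wanted, pass an explicit direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import NumericFailure
from .experiment import CONDITIONS, CopyingErrorSample, TransmissionRecord
from .moments import expected_variance
from .simulate import ChainEnsemble, simulate_ensemble

__all__ = [
    "NormalityResult",
    "EmpiricalPValueResult",
    "DEFAULT_PVALUE_SEED",
    "estimate_sigma",
    "anderson_darling_normality",
    "final_chain_stats",
    "empirical_p_value",
]

#: default seed of the Monte-Carlo null when the caller does not supply one
DEFAULT_PVALUE_SEED = 987654321

AD_VARIANT = "composite normal (estimated mean/sd), Stephens small-sample correction, case-3 p"


@dataclass(frozen=True)
class NormalityResult:
    """Anderson-Darling test outcome for a sample of error ratios."""

    statistic: float  # uncorrected A^2
    p_value: float
    n: int
    variant: str = AD_VARIANT


@dataclass(frozen=True)
class EmpiricalPValueResult:
    """Monte-Carlo comparison of an observed chain statistic to the model."""

    observed: float
    predicted: float
    direction: str  # "above" or "below"
    p_value: float
    reps: int
    seed: int
    statistic: str


def estimate_sigma(sample: CopyingErrorSample, scope: str = "per_condition"
                   ) -> dict[str, float]:
    """Sample sd (n-1) of the copying-error ratios.

    ``scope="per_condition"`` returns ``{condition: sd}`` for each
    condition present.  ``scope="pooled"`` returns both defensible overall
    summaries — ``{"sd_all_ratios": ..., "mean_of_condition_sds": ...}`` —
    since "the overall sd" of a two-condition experiment is ambiguous
    between the sd of all ratios about the grand mean and the average of
    the two condition sds.
    """
    if scope == "per_condition":
        out = {}
        for cond in CONDITIONS:
            ratios = sample.for_condition(cond)
            if ratios.size == 0:
                continue
            if ratios.size < 2:
                raise ValueError(f"need >= 2 ratios in condition {cond!r}, got {ratios.size}")
            out[cond] = float(ratios.std(ddof=1))
        if not out:
            raise ValueError("sample contains no recognized condition labels")
        return out
    if scope == "pooled":
        if len(sample) < 2:
            raise ValueError(f"need >= 2 ratios, got {len(sample)}")
        per = estimate_sigma(sample, scope="per_condition")
        return {
            "sd_all_ratios": float(sample.ratios.std(ddof=1)),
            "mean_of_condition_sds": float(np.mean(list(per.values()))),
        }
    raise ValueError(f"scope must be 'per_condition' or 'pooled', got {scope!r}")


def anderson_darling_normality(sample: np.ndarray) -> NormalityResult:
    """Anderson-Darling test of normality with estimated mean and variance.

    Computes the A^2 statistic from the probability-integral transform of
    the standardized order statistics,

        A^2 = -n - (1/n) * sum_i (2i-1) * [ln F(z_(i)) + ln(1 - F(z_(n+1-i)))],

    then evaluates the p-value from the small-sample-corrected
    A* = A^2 (1 + 0.75/n + 2.25/n^2) with the published case-3 polynomial
    approximation (the variant implemented by R's ``nortest::ad.test``).
    The reported ``statistic`` is the uncorrected A^2.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError(f"Anderson-Darling p approximation needs n >= 8, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample is constant; normality test undefined")
    z = (x - x.mean()) / sd
    log_cdf = sps.norm.logcdf(z)
    log_sf = sps.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (log_cdf + log_sf[::-1]))

    a_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a_star < 0.2:
        p = 1.0 - np.exp(-13.436 + 101.14 * a_star - 223.73 * a_star**2)
    elif a_star < 0.34:
        p = 1.0 - np.exp(-8.318 + 42.796 * a_star - 59.938 * a_star**2)
    elif a_star < 0.6:
        p = np.exp(0.9177 - 4.279 * a_star - 1.38 * a_star**2)
    elif a_star < 10.0:
        p = np.exp(1.2937 - 5.709 * a_star + 0.0186 * a_star**2)
    else:
        p = 3.7e-24
    return NormalityResult(statistic=float(a2), p_value=float(np.clip(p, 0.0, 1.0)), n=n)


def _final_sizes_from_records(records: list[TransmissionRecord],
                              condition: str) -> np.ndarray:
    chains: dict[str, dict[int, float]] = {}
    for r in records:
        if r.condition == condition:
            chains.setdefault(r.chain_id, {})[r.generation] = r.produced_size_cm
    if not chains:
        raise ValueError(f"no records for condition {condition!r}")
    t_final = max(max(gens) for gens in chains.values())
    incomplete = sorted(c for c, gens in chains.items() if t_final not in gens)
    if incomplete:
        raise ValueError(
            f"chains {incomplete} in condition {condition!r} do not reach "
            f"generation {t_final}")
    return np.array([chains[c][t_final] for c in sorted(chains)])


def final_chain_stats(data: list[TransmissionRecord] | ChainEnsemble,
                      condition: str | None = None) -> tuple[float, float]:
    """Cross-chain mean and sample variance of sizes at the last generation.

    Accepts either experiment records (``condition`` required) or a
    simulated :class:`ChainEnsemble`.
    """
    if isinstance(data, ChainEnsemble):
        finals = data.sizes[:, -1]
    else:
        if condition is None:
            raise ValueError("condition is required for record input")
        finals = _final_sizes_from_records(data, condition)
    if finals.size < 2:
        raise ValueError("final variance requires at least 2 complete chains")
    return float(finals.mean()), float(finals.var(ddof=1))


def empirical_p_value(observed: float, statistic: str, sigma: float, *,
                      n_chains: int = 10, T: int = 10, x0: float = 10.0,
                      reps: int = 10_000, seed: int = DEFAULT_PVALUE_SEED,
                      direction: str = "auto") -> EmpiricalPValueResult:
    """Monte-Carlo empirical p-value of a final-generation chain statistic.

    Simulates ``reps`` independent replicas of the experimental design
    (``n_chains`` chains of ``T`` generations from ``x0``, copying-error
    sd ``sigma``), computes the chosen final statistic ("final_mean" or
    "final_variance") in each, and returns the proportion of replicas at
    least as extreme as ``observed`` — ties count as extreme.

    ``direction="auto"`` compares in the direction of the observed
    deviation from the model prediction (x0 for the mean,
    ``expected_variance(x0, sigma, T)`` for the variance); "above"/"below"
    force the tail.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if reps < 100:
        raise ValueError(f"reps must be >= 100 for a meaningful p-value, got {reps}")
    if statistic not in ("final_mean", "final_variance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if direction not in ("auto", "above", "below"):
        raise ValueError(f"direction must be auto/above/below, got {direction!r}")

    ens = simulate_ensemble(x0, sigma, reps * n_chains, T, seed)
    finals = ens.sizes[:, -1].reshape(reps, n_chains)
    if statistic == "final_mean":
        sims = finals.mean(axis=1)
        predicted = float(x0)
    else:
        sims = finals.var(axis=1, ddof=1)
        predicted = expected_variance(x0, sigma, T)

    if direction == "auto":
        direction = "above" if observed >= predicted else "below"
    if direction == "above":
        p = float(np.mean(sims >= observed))
    else:
        p = float(np.mean(sims <= observed))
    if not np.isfinite(p):
        raise NumericFailure("empirical p-value is not finite")
    return EmpiricalPValueResult(observed=float(observed), predicted=predicted,
                                 direction=direction, p_value=p, reps=reps,
                                 seed=seed, statistic=statistic)
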