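"""Ensembles of independent ACE transmission chains.

Each chain starts at ``x0`` and evolves by multiplying its current size by
an independent Normal(1, sigma^2) error ratio per generation.  Non-positive
draws are rejected and resampled (the rejection count is recorded; at
empirical sigma it is zero in practice, the truncation point being tens of
standard deviations below the mean).

Draws are consumed chain-major — all generations of chain 0, then chain 1,
and so on — from a single :class:`numpy.random.Generator` seeded per
ensemble, so a given (x0, sigma, n_chains, T, seed) tuple always yields a
bitwise-identical ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NumericFailure

__all__ = [
    "ChainEnsemble",
    "simulate_ensemble",
    "mean_trajectory",
    "variance_trajectory",
    "pooled_cv",
    "ensemble_to_csv",
    "ensemble_from_csv",
]


@dataclass
class ChainEnsemble:
    """Realized sizes of ``n_chains`` independent chains over T generations.

    ``sizes`` has shape (n_chains, T+1); column 0 is the seed value x0,
    column t the size after t transmission events.  All entries are
    strictly positive.
    """

    sizes: np.ndarray = field(repr=False)
    x0: float
    sigma: float | None
    seed: int | None
    resample_count: int = 0

    @property
    def n_chains(self) -> int:
        return self.sizes.shape[0]

    @property
    def T(self) -> int:
        return self.sizes.shape[1] - 1


def simulate_ensemble(x0: float, sigma: float, n_chains: int, T: int,
                      seed: int) -> ChainEnsemble:
    """Simulate ``n_chains`` independent multiplicative chains of length T.

    Parameters
    ----------
    x0:
        Seed size (cm), > 0.
    sigma:
        Copying-error ratio sd, >= 0 (0 gives a degenerate, error-free chain).
    n_chains, T:
        Ensemble dimensions; T = 0 yields only the seed column.
    seed:
        Seed of the per-ensemble random generator.
    """
    if x0 <= 0:
        raise ValueError(f"x0 must be > 0, got {x0}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n_chains < 1:
        raise ValueError(f"n_chains must be >= 1, got {n_chains}")
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")

    rng = np.random.default_rng(seed)
    eps = rng.normal(1.0, sigma, size=(n_chains, T))
    resampled = 0
    bad = eps <= 0.0
    while bad.any():
        n_bad = int(bad.sum())
        eps[bad] = rng.normal(1.0, sigma, size=n_bad)
        resampled += n_bad
        bad = eps <= 0.0

    sizes = np.empty((n_chains, T + 1))
    sizes[:, 0] = x0
    if T > 0:
        np.cumprod(eps, axis=1, out=eps)
        sizes[:, 1:] = x0 * eps
    return ChainEnsemble(sizes=sizes, x0=float(x0), sigma=float(sigma),
                         seed=int(seed), resample_count=resampled)


def mean_trajectory(ensemble: ChainEnsemble) -> np.ndarray:
    """Cross-chain arithmetic mean size (cm) at each generation 0..T."""
    if ensemble.n_chains < 1:
        raise ValueError("ensemble is empty")
    return ensemble.sizes.mean(axis=0)


def variance_trajectory(ensemble: ChainEnsemble) -> np.ndarray:
    """Cross-chain sample variance (cm^2, n-1 denominator) per generation."""
    if ensemble.n_chains < 2:
        raise ValueError("sample variance requires at least 2 chains")
    return ensemble.sizes.var(axis=0, ddof=1)


def pooled_cv(ensemble: ChainEnsemble, include_seed: bool = False) -> float:
    """Coefficient of variation of the pooled sizes across all chains.

    Pools every value from generations 1..T of every chain (the seed
    generation is excluded by default, since it is a constant that never
    entered the transmission process) and returns sd/mean with the n-1
    sd.  This is the summary the macroevolutionary calibration compares
    against archaeological size CVs.
    """
    if ensemble.T < 1:
        raise ValueError("pooled CV requires at least one generation (T >= 1)")
    start = 0 if include_seed else 1
    values = ensemble.sizes[:, start:].ravel()
    mean = values.mean()
    if mean <= 0:
        raise NumericFailure(f"pooled mean is non-positive ({mean}); CV undefined")
    return float(values.std(ddof=1) / mean)


def ensemble_to_csv(ensemble: ChainEnsemble, path: str | Path) -> None:
    """Write the ensemble in long format (chain, generation, size_cm)."""
    n, t1 = ensemble.sizes.shape
    frame = pd.DataFrame({
        "chain": np.repeat(np.arange(n), t1),
        "generation": np.tile(np.arange(t1), n),
        "size_cm": ensemble.sizes.ravel(),
    })
    frame.to_csv(path, index=False)


def ensemble_from_csv(path: str | Path) -> ChainEnsemble:
    """Read a long-format ensemble CSV back into a :class:`ChainEnsemble`.

    Provenance fields (sigma, seed) are not stored in the CSV and come
    back as ``None``.
    """
    frame = pd.read_csv(path)
    wide = frame.pivot(index="chain", columns="generation", values="size_cm")
    sizes = wide.sort_index().to_numpy()
    x0 = float(sizes[0, 0])
    return ChainEnsemble(sizes=sizes, x0=x0, sigma=None, seed=None)
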