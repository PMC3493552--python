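"""Synthetic transmission-chain experiments.

Generates datasets with the structure and statistical assumptions of the
touch-screen resizing experiment: two conditions ("larger"/"smaller"
initial size of the image the participant resizes), 10 chains of 10
participants per condition, a 10 cm seed image, produced sizes bounded by
the 14.4 cm screen, and multiplicative normal copying error of sd sigma.
An optional per-condition bias shifts the error-ratio mean away from 1
(produced = target * r, r ~ Normal(1 + bias, sigma^2)), emulating the
observed tendency of the initial image size to pull the produced size in
its direction; the default bias is 0 (the unbiased ACE null).

The generator emulates the error model the analysis assumes — it does not
model participant heterogeneity in Weber fractions, within-chain error
correlation, or any device artifact, so agreement of the analysis with
generated data validates the pipeline's arithmetic, not those aspects of
real behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .experiment import (CONDITIONS, SCREEN_MAX_CM, SEED_SIZE_CM,
                         TransmissionRecord)

__all__ = ["SyntheticDesign", "SyntheticExperiment", "generate_experiment",
           "generate_biased_pair"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic experiment (defaults = the study design)."""

    sigma: float = 0.0343
    bias: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in CONDITIONS})
    n_chains_per_condition: int = 10
    generations: int = 10
    x0: float = SEED_SIZE_CM
    screen_max: float = SCREEN_MAX_CM
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.x0 <= self.screen_max):
            raise ValueError(f"x0 must lie in (0, screen_max={self.screen_max}], got {self.x0}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        for cond, b in self.bias.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in bias")
            if 1.0 + b <= 0:
                raise ValueError(f"bias {b} gives non-positive mean error ratio")


@dataclass
class SyntheticExperiment:
    """Generated records plus generation diagnostics.

    Iterable over its :class:`TransmissionRecord` list, so it can be
    passed anywhere a record collection is expected.
    """

    records: list[TransmissionRecord]
    design: SyntheticDesign
    clip_count: int = 0
    resample_count: int = 0

    def __iter__(self) -> Iterator[TransmissionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def generate_experiment(design: SyntheticDesign) -> SyntheticExperiment:
    """Generate one synthetic two-condition transmission-chain experiment.

    Each chain starts at ``design.x0``; every produced size is the target
    times an independent Normal(1 + bias, sigma^2) ratio, resampled if
    non-positive and clipped to the screen height (both events counted —
    at study-scale sigma neither occurs in practice).  The produced size
    of generation g becomes the target of generation g+1, so the output
    always satisfies the experiment-schema invariants.
    """
    rng = np.random.default_rng(design.seed)
    records: list[TransmissionRecord] = []
    clip_count = 0
    resample_count = 0
    n = design.n_chains_per_condition
    for condition in CONDITIONS:
        mu = 1.0 + design.bias.get(condition, 0.0)
        ratios = rng.normal(mu, design.sigma, size=(n, design.generations))
        bad = ratios <= 0.0
        while bad.any():
            n_bad = int(bad.sum())
            ratios[bad] = rng.normal(mu, design.sigma, size=n_bad)
            resample_count += n_bad
            bad = ratios <= 0.0
        current = np.full(n, design.x0)
        for g in range(1, design.generations + 1):
            produced = current * ratios[:, g - 1]
            over = produced > design.screen_max
            if over.any():
                clip_count += int(over.sum())
                produced = np.minimum(produced, design.screen_max)
            for c in range(n):
                records.append(TransmissionRecord(
                    condition=condition, chain_id=f"{condition[0]}{c + 1:02d}",
                    generation=g, target_size_cm=float(current[c]),
                    produced_size_cm=float(produced[c])))
            current = produced
    if clip_count or resample_count:
        logger.warning("synthetic generation: %d clip, %d resample events",
                       clip_count, resample_count)
    return SyntheticExperiment(records=records, design=design,
                               clip_count=clip_count,
                               resample_count=resample_count)


def generate_biased_pair(sigma: float, bias_larger: float, bias_smaller: float,
                         seed: int = 0, **overrides) -> SyntheticExperiment:
    """Two-condition dataset with opposite mean drifts.

    ``bias_larger > 0`` makes the larger-condition chains drift upward in
    expectation (final mean x0*(1+bias)^T) and ``bias_smaller < 0`` the
    smaller-condition chains downward, while leaving the error variance
    untouched — the scenario in which the empirical p-value should flag
    the final mean but not the final variance.
    """
    design = SyntheticDesign(sigma=sigma,
                             bias={"larger": bias_larger, "smaller": bias_smaller},
                             seed=seed, **overrides)
    return generate_experiment(design)
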