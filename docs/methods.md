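# Methods

## Model and assumptions

The accumulated copying error (ACE) model treats the size of a culturally
transmitted artifact as a multiplicative random walk. Each generation,
one individual copies the previous individual's artifact; Weber's law
implies the copying error is proportional to the size being copied, so

    X_t = X_{t-1} · ε_t ,   ε_t ~ i.i.d. Normal(1, σ²),   X_0 = x0.

Assumptions: errors are independent across generations and chains,
identically distributed (no participant heterogeneity in Weber
fraction), unbiased (mean ratio exactly 1), and normal (a central-limit
argument over many elementary perceptual comparisons). The moments
follow from E[ε] = 1 and E[ε²] = 1 + σ²:

    E[X_t] = x0,          Var[X_t] = x0²·((1 + σ²)^t − 1).

For σ²t ≪ 1 the variance is ≈ x0²·t·σ², so alternative formulations that
are linear in t are indistinguishable at experimental scales; the
exponential regime only matters at deep time depths.

A normal ratio can in principle be non-positive. `truncated_error_moments`
evaluates the mean and sd of the zero-truncated normal (via
`scipy.stats.truncnorm`): at σ ≤ 0.1 the truncation point lies ≥ 10
standard deviations below the mean and the moment shift is < 10⁻²⁰, so
the untruncated closed forms are used throughout. The simulator
nevertheless guarantees positivity by rejecting and resampling
non-positive draws, counting the (in practice zero) rejections.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| σ (copy-error sd) | 0.0343 | ratio | overall sd measured in the resizing experiment; close to the ~3% Weber fraction for line length |
| x0 | 10 cm (experiments), 1 (calibration) | size | seed image height; calibration follows the standard 1-seeded form (the pooled CV is scale-invariant) |
| screen bound | 14.4 cm | size | physical display height; produced sizes are clipped there |
| chains × generations | 10 × 10 per condition | — | the experimental design |
| calibration ensemble | 100 chains | — | the standard pooled-CV simulation form |
| replicates (calibration) | 25 | — | median over replicates removes the seed lottery of a single ensemble while keeping the quoted procedure's scale |
| generation time | 20 | years | conventional human generation length |
| empirical p reps | 10,000 | — | Monte-Carlo resolution of 10⁻⁴ |

## Statistical procedures

**σ estimation.** Sample sd (n−1) of the produced/target ratios. "The
overall σ" of a two-condition experiment is ambiguous, so the pooled
scope reports both candidates: the sd of all 200 ratios about the grand
mean, and the mean of the two condition sds.

**Normality.** Anderson–Darling for the composite normal null (mean and
variance estimated), computed from the probability-integral transform of
the standardized order statistics; p-values use the Stephens small-sample
correction A* = A²(1 + 0.75/n + 2.25/n²) and the published case-3
polynomial approximation. This is the variant implemented by R's
`nortest::ad.test`, against which the implementation is cross-checked in
the test suite to 10⁻⁹. The reported statistic is the uncorrected A²;
the variant label travels with every result.

**Empirical p-values.** The experimental design (10 chains × 10
generations, x0 = 10 cm, the condition's measured σ) is simulated `reps`
times; p is the proportion of simulated final means (or final sample
variances) at least as extreme as the observed value, ties counting as
extreme. The default direction ("auto") is the side of the observed
deviation from the model prediction (x0, or the closed-form variance).
Because either tail can then produce a small p, the null rate of
p < α is ≈ 2α; this is inherent to direction-picking procedures. For
calibration studies requiring a uniform null p, the direction can be
fixed ("above"/"below") — the uniformity checks in the test suite use
the fixed-direction form, the only one for which uniformity can hold.

**Pooled-CV calibration.** The pooled CV (sd/mean of all values from all
generations 1..T of all chains; the constant seed value is excluded) has
no tractable closed form, so it is simulated: 100 chains, x0 = 1. Both
solvers operate on the median over 25 independently seeded replicate
ensembles and report the replicate spread.

- `generations_to_cv`: one simulation pass per replicate yields the CV at
  *every* horizon t ≤ max_T via cumulative sums of values and squares;
  the result is the first horizon where the median CV curve reaches the
  target, or an explicit not-reached report.
- `sigma_for_cv`: geometric bisection on σ. Common random numbers (each
  replicate's standard-normal draws fixed by its child seed, ε = 1 + σz)
  make the objective deterministic and monotone in σ. The starting
  bracket comes from the continuous-time approximation
  pooled Var ≈ (e^g − 1)/g − 1 with g = σ²T; iteration stops when the
  achieved median CV is within 2% (relative) of the target. With a good
  initial guess the first midpoint may already satisfy the tolerance —
  the simulation still verifies it. Bracketing failure (target CV
  unattainable) raises an error reporting the achievable CV range.

## Synthetic data generator

`generate_experiment` emulates the structure of the resizing experiment:
two conditions, 10 chains × 10 generations each, seed image 10 cm,
produced = target × r with r ~ Normal(1 + bias, σ²), produced sizes
clipped to (0, 14.4] cm (clip and resample events are counted; at default
parameters both are zero). The per-condition `bias` shifts the error-ratio
mean additively — the simplest mechanism consistent with the
multiplicative model — emulating the observed pull of the initial image
size on the produced size; its default is 0 (the unbiased null) because
only the direction of the real effect is known, not its magnitude.
`generate_biased_pair` builds the two-sided biased scenario (larger
condition drifting up, smaller drifting down) used to verify that the
empirical p-value flags a mean deviation while the variance stays
consistent with the null.

What the generator does **not** emulate: participant-level heterogeneity
in Weber fractions, correlation of errors within a chain, rounding or
quantization of the touch interface, and any device-specific biasing
mechanism. Tests passing on generated data therefore validate the
pipeline's statistics under the model's assumptions, not those aspects of
real behavior.

## Numerical choices

- Sample variances and sds use the n−1 denominator throughout.
- Generation indexing: t = 0 is the seed value; the first copy is t = 1.
- `expected_variance` overflows to `inf` with a warning at extreme t
  rather than saturating silently.
- One seeded `numpy.random.Generator` per ensemble; draws are consumed
  chain-major (all generations of chain 0, then chain 1, …), so identical
  seeds give bitwise-identical ensembles.
- Calibration child seeds derive from `numpy.random.SeedSequence.spawn`.
- Chain-linkage validation uses a 10⁻⁶ relative tolerance when ingesting
  external CSVs (source-file rounding), but is strict before writing.
- CSV reads use round-trip float parsing so write→read is an identity.

## Problem sizes

The verification suite uses 10⁵ chains for the moment checks at T = 10,
10⁴ chains at T = 400 for the mean/median asymmetry, 500 replicate
experiments for σ-recovery coverage, 200 null draws × 2,000 Monte-Carlo
reps for p-value calibration, and the full 60,000-generation × 100-chain
× 25-replicate ensemble for the deep-time σ inversion — sizes at which
Monte-Carlo error is comfortably inside each check's tolerance.

## Known limitations

- Chains are independent: no branching, merging, or spatial structure,
  so the calibration treats the archaeological sample as if produced by
  parallel isolated lineages.
- The pooled-CV comparison consumes archaeological CVs as printed scalar
  summaries; it does not model the database's temporal or regional
  structure.
- The empirical p-value is one-sided by design; no two-sided or
  multiplicity-corrected variant is provided.
- The Anderson–Darling p approximation is only valid for n ≥ 8, and the
  test requires non-degenerate samples.
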