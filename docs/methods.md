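# Methods

## Model

`polyadapt` simulates and analyzes a perfectly heritable quantitative trait
controlled additively by *l* unlinked diallelic loci in a randomly mating
diploid population of finite size *N*. The + allele at locus *i* contributes
+γᵢ/2 to the phenotype, the − allele −γᵢ/2. With pᵢ the + allele frequency
and qᵢ = 1 − pᵢ, the first three cumulants of the genotypic-value
distribution are

    c₁ = Σ γᵢ (2pᵢ − 1)
    c₂ = 2 Σ γᵢ² pᵢqᵢ
    c₃ = 2 Σ γᵢ³ pᵢqᵢ (qᵢ − pᵢ)

Fitness is Gaussian about the optimum, w(z) = exp(−(s/2)(z − z_opt)²), with
1/s assumed large relative to the phenotypic variance. Selection and
symmetric mutation (rate μ = ν per locus per generation) give the
deterministic per-generation change

    dpᵢ/dt = −sγᵢpᵢqᵢ Δc₁ − (sγᵢ²/2) pᵢqᵢ(qᵢ − pᵢ) − μpᵢ + νqᵢ,

where Δc₁ = c₁ − z_opt: a directional term pulling the mean toward the
optimum, a stabilizing (disruptive-on-frequencies) term, and mutation
pressure. Drift is added by binomial resampling of 2N gene copies per locus
per generation, independently across loci (free recombination justifies
locus independence; loci remain coupled through Δc₁, which every replicate
recomputes from its own frequencies each generation). The conditional
variance of the binomial step, p*(1 − p*)/2N, is exactly the diffusion's
drift variance.

### Fast/slow decomposition and stationary theory

The mean deviation Δc₁ relaxes at rate s·c₂ — far faster than individual
allele frequencies — so it sits at a quasi-equilibrium

    Δc̃₁ = −((s/2) c̃₃ + 2μz₀) / (s c̃₂ + 2μ).

Treating Δc̃₁ as a constant in the per-locus diffusion gives Wright's
stationary density for each locus,

    f(p) ∝ p^(2β−1) q^(2β−1) exp(−2αγ Δc̃₁ p − αγ² pq),   α = 2Ns, β = 2Nμ,

which is strongly U-shaped for β < 1/2: at realistic mutation rates most
loci sit near fixation or loss, in sharp contrast with the intermediate
equilibria of the infinite-population model. The package always normalizes
this density by adaptive quadrature under p = sin²θ (which removes the
integrable endpoint singularities); the linearized beta-function
normalization is exposed only as the approximation it is and is tested
against quadrature, never used as the normalizer.

Because Δc̃₁ appears inside the density whose moments determine c̃₂ and c̃₃,
which in turn determine Δc̃₁, the equilibrium is found by damped fixed-point
iteration (damping 0.5, tolerance 1e-8 on the deviation, followed by
undamped polishing). Moments during the iteration use fixed 600-node
Gauss–Legendre quadrature on the θ grid, vectorized over loci (valid for
β ≥ 1/4, where the transformed integrand is bounded; smaller β falls back to
adaptive quadrature per locus).

### Optimum shift

After a sudden shift z₀ → z_f at t = 0 the mean approaches the new optimum
exponentially at a rate proportional to the pre-shift variance (Lande's
classical result):

    Δc₁(t) ≈ Δc₁(0) exp(−s c₂(0) t),

and the short-term phase lasts ≈ 1/(s c₂(0)) generations. During this phase
the per-locus ensemble moments obey (directional selection and drift only)

    dE[p]/dt  = −sγ E[pq] Δc₁(t)
    dE[p²]/dt = −2sγ E[p²q] Δc₁(t) + E[pq]/2N,

a hierarchy that does not close; the package exposes the right-hand sides
with the third moment supplied by the caller. The deterministic end-of-phase
frequency shift, δpᵢ ≈ −γᵢpᵢ(0)qᵢ(0) Δc₁(0)(1 − e⁻¹)/c₂(0), is accurate for
small effects and intermediate starting frequencies; drift degrades it first
at loci near the frequency boundaries.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| s | 0.1 | 1/(trait units)² | weak stabilizing selection, 1/s ≫ c₂ |
| l | 200 | loci | highly polygenic architecture |
| γ̄ | 0.01 | trait units | exponential effect sizes, mean well below the small-effect threshold 2√(2μ/s) ≈ 0.028 |
| μ = ν | 1e-5 | /locus/generation | standard eukaryotic per-locus rate; β = 2Nμ = 0.4 at N = 20,000 (U-shaped regime) |
| z₀ → z_f | 0.2 → 0.5 | trait units | both within the attainable range (±lγ̄ = ±2) |
| N | 20,000 (and 5000, 10,000; bottleneck to 3000) | diploids | human-calibrated |
| burn-in | 4N generations | — | experiment default; see below |

These parameter values are the package's standard human-calibrated
conditions and are encoded verbatim in the experiment presets.

## Synthetic-data generator

All inputs are generated internally; there is no external data. An
experiment samples one architecture (shared by every replicate — replicate
averaging is over drift realizations, not architectures) with exponentially
distributed effect sizes. The experiment layer draws that sample by
stratified inversion (inverse CDF over jittered strata, shuffled, then
normalized to the exact nominal mean): the realized architecture is then
representative of the nominal distribution, whereas a raw i.i.d. draw of 200
effects carries ~16% standard deviation in Σγᵢ², which would propagate
one-for-one into every variance-level result. `sample_effects` itself
remains a plain i.i.d. sampler.

Replicate ensembles start either from an explicit state or from per-locus
draws of the self-consistent stationary density (rejection sampling from a
Beta(2β, 2β) proposal with an exact envelope). The stationary start makes
equilibrium experiments cheap: the ensemble variance matches the
self-consistent theory at t = 0 and relaxes within a few thousand
generations to the Wright–Fisher equilibrium, which sits ~2% above the
mean-field value at N = 20,000.

What the generator does not emulate: linkage and hitchhiking of neutral
sites, dominance, epistasis, pleiotropy, environmental variance, unequal
mutation rates in the stationary theory, and inter-locus correlations at
initialization (loci are drawn independently; the joint equilibrium's weak
correlations through Δc₁ build up during burn-in). Passing tests therefore
validate the allele-frequency-level model, not sequence-level signatures.

## Numerical choices

- One Euler step per generation everywhere (dt = 1), matching the
  Wright–Fisher clock; the per-generation rates (sγ², μ ≪ 1) make finer
  steps irrelevant at the tolerances used.
- Frequencies are clipped to [0, 1] after the deterministic update; with
  μ = ν > 0 the flow is inward at the boundaries, so the clip is only a
  numerical guard. Fixed loci stay in the system (mutation can
  re-polymorphize them).
- Update order within a generation: selection + mutation, then binomial
  drift — the diffusion's infinitesimal mean/variance pairing.
- The simulator advances all replicates as one (replicates × loci) matrix
  under a single seeded generator: identical (seed, replicate count) gives
  bit-identical output, and the vectorized binomial sampling is ~3× faster
  than per-replicate streams, which is what makes the full experiment
  presets affordable on one CPU.
- Quadratures: `epsabs 1e-11 / epsrel 1e-9`, subdivision limit 200; the
  self-consistency residual of the equilibrium solver is driven below 1e-10.
- The quasi-equilibrium formula accepts c₃ explicitly; callers may pass 0
  for the very-small-effects limit. The default everywhere is to include it.

## Phase statistics for demographic experiments

For a piecewise-constant demography the bottleneck report averages Δc₁ over
the *whole* of each epoch. A bottleneck is a transient — the lag deepens
throughout it (from ≈ −0.0022 toward the much deeper N = 3000 equilibrium
value ≈ −0.011, which a 5000-generation bottleneck never reaches) — so the
full-phase average is "the average state the population experienced during
the phase"; end-weighted windows give systematically deeper values (≈ −0.005
for the last quarter versus ≈ −0.0042 for the full phase at these
parameters). The genetic variance at the end of the bottleneck is reported
at the final bottleneck generation. Per-replicate phase-averaged Δc₁
fluctuates with standard deviation ≈ √(1/2Ns) (≈ 0.04 during the
bottleneck), so ratios of phase averages carry Monte-Carlo error of tens of
percentage points even at 2000 replicates; point values of c₂ are far more
precise because they average 200 loci.

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the equilibrium targets at their full setups
(100–200 replicates, 4N-generation burn-ins) and the bottleneck at 2000
replicates with a 3000-generation recorded pre-bottleneck phase; because
runs start from the stationary density, a long pre-phase adds nothing (the
trait-mean relaxation time is ≈ 1/(s c₂) ≈ 1100 generations). The pytest
suite uses the same designs with burn-ins of 6000–10,000 generations and
2500 pre-bottleneck generations, chosen as several multiples of every
relaxation time that matters for time-averaged statistics.

## Known limitations

- The self-consistent theory is mean-field in Δc̃₁; the simulated
  equilibrium variance exceeds it by ~2% at N = 20,000, and the simulated
  mean deviation is ~40% deeper than the quasi-equilibrium prediction (the
  same direction and size of discrepancy the analytic approximation shows
  against any faithful simulation of this model).
- Equilibrium variance levels inherit the realized Σγᵢ² of the sampled
  architecture; two studies drawing different 200-locus architectures can
  legitimately differ by ~10% in c̃₂ even at identical nominal parameters.
- The stationary density assumes symmetric mutation; the simulator accepts
  μ ≠ ν but no analytic machinery covers that case.
- The moment hierarchy of the short-term phase is not closed; the package
  deliberately provides right-hand sides, not a solver, for it.
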