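"""Deterministic and moment-level dynamics of the polygenic trait.

Three layers of approximation to the allele-frequency dynamics live here:

1. The exact deterministic (infinite-population) per-generation change at
   locus *i*,

   ``dp_i/dt = -s g_i p_i q_i dc1 - (s g_i^2 / 2) p_i q_i (q_i - p_i)
              - mu p_i + nu q_i``,

   where ``dc1 = c1 - z_opt`` is the deviation of the mean from the current
   optimum.  The first term is directional selection toward the optimum, the
   second stabilizing selection near it, the last two symmetric mutation.

2. A fast/slow decomposition: the mean deviation ``dc1`` relaxes much faster
   than individual allele frequencies, so it sits at a quasi-equilibrium
   value determined by the (slow) variance and skewness,

   ``dc1~ = -((s/2) c3 + 2 mu z0) / (s c2 + 2 mu)``.

   After a sudden optimum shift the mean approaches the new optimum
   exponentially at a rate proportional to the pre-shift genetic variance
   (Lande's classical result): ``dc1(t) = dc1(0) exp(-s c2(0) t)``.  The
   "short-term phase" of adaptation lasts about ``1 / (s c2(0))``
   generations.

3. Moment equations for the allele-frequency ensemble during the short-term
   phase, derived from the Kolmogorov backward operator with directional
   selection and drift only (stabilizing selection and mutation are
   negligible while the population is far from the new optimum):

   ``dE[p]/dt   = -s g E[pq] dc1(t)``
   ``dE[p^2]/dt = -2 s g E[p^2 q] dc1(t) + E[pq] / (2N)``
   ``dE[pq]/dt  =  dE[p]/dt - dE[p^2]/dt``

   The hierarchy does not close (``E[p^2 q]`` appears), so the third moment
   is supplied by the caller, typically estimated from simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trait_model import (
    PopulationState,
    SelectionRegime,
    TraitArchitecture,
    cumulants_from_freqs,
)

__all__ = [
    "MomentState",
    "DeterministicTrajectory",
    "allele_velocity",
    "integrate_deterministic",
    "quasi_equilibrium_deviation",
    "mean_deviation_trajectory",
    "short_term_duration",
    "moment_rhs",
    "short_term_shift",
]


@dataclass(frozen=True)
class MomentState:
    """Low-order moments of the allele-frequency distribution at one locus.

    ``e_pq`` is derived as ``e_p - e_p2`` on construction; the higher moment
    ``e_p2q = E[p^2 (1-p)]`` must be supplied because the moment hierarchy
    does not close.
    """

    e_p: float
    e_p2: float
    e_p2q: float
    e_pq: float = None  # type: ignore[assignment]  # derived

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_p <= 1.0:
            raise ValueError(f"E[p] must lie in [0,1], got {self.e_p}")
        if self.e_p2 > self.e_p + 1e-12 or self.e_p2 < self.e_p**2 - 1e-12:
            raise ValueError(
                f"E[p^2]={self.e_p2} violates E[p]^2 <= E[p^2] <= E[p] with E[p]={self.e_p}"
            )
        derived = self.e_p - self.e_p2
        if self.e_pq is not None and abs(self.e_pq - derived) > 1e-12:
            raise ValueError("e_pq must equal e_p - e_p2")
        object.__setattr__(self, "e_pq", derived)


def allele_velocity(
    state: PopulationState,
    arch: TraitArchitecture,
    regime: SelectionRegime,
    delta_c1: float,
) -> np.ndarray:
    """Per-generation deterministic frequency change at every locus.

    ``delta_c1`` must be the current deviation of the trait mean from the
    current optimum.
    """
    p = state.freqs
    g = arch.effects
    if p.size != g.size:
        raise ValueError(f"state has {p.size} loci, architecture {g.size}")
    q = 1.0 - p
    pq = p * q
    s = regime.s
    return (
        -s * g * pq * delta_c1
        - 0.5 * s * g**2 * pq * (q - p)
        - arch.mu_fwd * p
        + arch.mu_bwd * q
    )


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Forward-Euler trajectory of frequencies and cumulants."""

    generations: np.ndarray  # (T+1,)
    freqs: np.ndarray  # (T+1, l)
    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    delta_c1: np.ndarray  # c1 - optimum at each generation

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(self.freqs[-1], generation=int(self.generations[-1]))


def integrate_deterministic(
    state0: PopulationState,
    arch: TraitArchitecture,
    regime: SelectionRegime,
    n_generations: int,
) -> DeterministicTrajectory:
    """Integrate the deterministic dynamics with one Euler step per generation.

    The mean deviation is recomputed from the cumulants every generation, and
    frequencies are clipped to [0, 1] (with symmetric mutation the flow is
    inward at the boundaries, so the clip is only a numerical guard).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    l = state0.n_loci
    t0 = state0.generation
    gens = np.arange(t0, t0 + n_generations + 1)
    traj = np.empty((n_generations + 1, l))
    c1s = np.empty(n_generations + 1)
    c2s = np.empty(n_generations + 1)
    c3s = np.empty(n_generations + 1)
    p = state0.freqs.copy()
    for k, t in enumerate(gens):
        c1, c2, c3 = cumulants_from_freqs(p, arch.effects)
        traj[k] = p
        c1s[k], c2s[k], c3s[k] = c1, c2, c3
        if k < n_generations:
            dc1 = c1 - float(regime.optimum_at(t))
            v = allele_velocity(PopulationState(p, generation=int(t)), arch, regime, dc1)
            p = np.clip(p + v, 0.0, 1.0)
    dc1s = c1s - np.asarray(regime.optimum_at(gens), dtype=float)
    return DeterministicTrajectory(gens, traj, c1s, c2s, c3s, dc1s)


def quasi_equilibrium_deviation(
    c2: float,
    c3: float,
    regime: SelectionRegime,
    mu: float,
    optimum: float | None = None,
) -> float:
    """Quasi-equilibrium deviation of the trait mean from the optimum.

    With the mean treated as a fast variable relative to the allele
    frequencies, setting its rate of change to zero gives

    ``dc1~ = -((s/2) c3 + 2 mu z0) / (s c2 + 2 mu)``.

    The skewness contribution ``c3`` may be passed as 0 to recover the
    small-effects limit.  Note the mean never converges exactly to the
    optimum: mutation pressure and skewness hold it slightly off.
    """
    if c2 < 0:
        raise ValueError("genetic variance c2 cannot be negative")
    z0 = regime.z_initial if optimum is None else optimum
    denom = regime.s * c2 + 2.0 * mu
    if denom == 0.0:
        raise ZeroDivisionError(
            "degenerate input: s*c2 + 2*mu = 0, quasi-equilibrium undefined"
        )
    return -(0.5 * regime.s * c3 + 2.0 * mu * z0) / denom


def mean_deviation_trajectory(delta_c1_0: float, c2_0: float, s: float, t):
    """Exponential approach of the mean to a newly shifted optimum.

    ``dc1(t) = dc1(0) exp(-s c2(0) t)`` with t in generations since the
    shift; exact solution of ``d(dc1)/dt = -s c2 dc1`` at constant variance.
    """
    return delta_c1_0 * np.exp(-s * c2_0 * np.asarray(t, dtype=float))


def short_term_duration(s: float, c2_0: float) -> float:
    """Length of the rapid phase of adaptation, ``1 / (s c2(0))`` generations."""
    rate = s * c2_0
    if rate <= 0:
        raise ValueError(
            f"s*c2 must be positive to define the short-term phase, got {rate}"
        )
    return 1.0 / rate


def moment_rhs(m: MomentState, gamma: float, s: float, delta_c1: float, N: int):
    """Instantaneous rates of change of (E[p], E[p^2], E[pq]) at one locus.

    Valid during the short-term phase, where directional selection and drift
    dominate.  Returns a 3-tuple; the third entry equals the first minus the
    second identically.
    """
    if N <= 0:
        raise ValueError(f"population size must be positive, got {N}")
    sel = s * gamma * delta_c1
    d_ep = -sel * m.e_pq
    d_ep2 = -2.0 * sel * m.e_p2q + m.e_pq / (2.0 * N)
    d_epq = -sel * m.e_pq + 2.0 * sel * m.e_p2q - m.e_pq / (2.0 * N)
    return d_ep, d_ep2, d_epq


def short_term_shift(
    p0: np.ndarray,
    arch: TraitArchitecture,
    delta_c1_0: float,
    c2_0: float,
) -> np.ndarray:
    """Deterministic per-locus frequency shift over the short-term phase.

    For sufficiently small effects the frequency change accumulated over the
    ``1/(s c2(0))`` generations after the shift is approximately

    ``dp_i = -g_i p_i(0) q_i(0) dc1(0) (1 - 1/e) / c2(0)``.

    Every shift carries the sign of ``-dc1(0)``: the alleles move coherently
    in the direction demanded by the new optimum, with magnitude controlled
    by the compound parameter ``g_i p_i(0) q_i(0)``.
    """
    if c2_0 <= 0:
        raise ValueError("pre-shift genetic variance must be positive")
    p0 = np.asarray(p0, dtype=float)
    return -arch.effects * p0 * (1.0 - p0) * delta_c1_0 * (1.0 - np.exp(-1.0)) / c2_0
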