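"""Core types for an additive polygenic trait under Gaussian stabilizing selection.

The trait is perfectly heritable and controlled additively (no dominance or
epistasis) by ``l`` unlinked diallelic loci in a randomly mating diploid
population.  The trait-increasing (+) allele at locus *i* contributes
``+gamma_i/2`` to the phenotype and the - allele ``-gamma_i/2``, so a
homozygote spans ``[-gamma_i, +gamma_i]`` and the population mean lies in
``[-sum(gamma), +sum(gamma)]``.  Under Hardy-Weinberg and linkage equilibrium
the first three cumulants of the genotypic-value distribution are simple
polynomial functions of the + allele frequencies ``p_i``::

    c1 = sum_i gamma_i (2 p_i - 1)
    c2 = 2 sum_i gamma_i^2 p_i q_i
    c3 = 2 sum_i gamma_i^3 p_i q_i (q_i - p_i)       with q_i = 1 - p_i

Fitness of an individual with trait value ``z`` is Gaussian about the current
optimum, ``w(z) = exp(-(s/2) (z - z_opt)^2)``, where ``1/s`` is assumed large
relative to the phenotypic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "TraitArchitecture",
    "PopulationState",
    "SelectionRegime",
    "CumulantTriple",
    "DimensionMismatchError",
    "compute_cumulants",
    "cumulants_from_freqs",
    "fitness",
    "sample_effects",
    "threshold_effect",
]


class DimensionMismatchError(ValueError):
    """A frequency vector and an architecture have incompatible lengths."""


def sample_effects(
    l: int, mean_effect: float, seed: Union[int, np.random.Generator]
) -> np.ndarray:
    """Draw ``l`` i.i.d. exponential effect sizes with the given mean.

    An exponential effect-size distribution is the standard assumption for a
    highly polygenic architecture: many loci of small effect, few of large
    effect.  Reproducible for a fixed integer seed.
    """
    if l <= 0:
        raise ValueError(f"number of loci must be positive, got {l}")
    if mean_effect <= 0:
        raise ValueError(f"mean effect must be positive, got {mean_effect}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.exponential(mean_effect, size=l)


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture: per-locus effect sizes and symmetric mutation rates.

    Parameters
    ----------
    effects
        Per-locus effect sizes ``gamma_i > 0`` in phenotypic units.
    mu_fwd
        Mutation probability per generation from the + to the - allele.
    mu_bwd
        Mutation probability per generation from the - to the + allele.
        Equal forward and backward rates are assumed throughout the analytic
        theory; unequal rates are accepted by the simulator only.
    """

    effects: np.ndarray
    mu_fwd: float = 1e-5
    mu_bwd: float = 1e-5

    def __post_init__(self) -> None:
        eff = np.atleast_1d(np.asarray(self.effects, dtype=float))
        if eff.ndim != 1 or eff.size == 0:
            raise ValueError("effects must be a non-empty 1-D vector")
        if not np.all(np.isfinite(eff)) or np.any(eff <= 0):
            raise ValueError("all effect sizes must be strictly positive and finite")
        for name in ("mu_fwd", "mu_bwd"):
            m = getattr(self, name)
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {m}")
        object.__setattr__(self, "effects", eff)

    @classmethod
    def sampled(
        cls,
        n_loci: int,
        mean_effect: float,
        mu: float = 1e-5,
        seed: Union[int, np.random.Generator] = 0,
    ) -> "TraitArchitecture":
        """Architecture with exponentially distributed effects and mu = nu."""
        return cls(sample_effects(n_loci, mean_effect, seed), mu_fwd=mu, mu_bwd=mu)

    @property
    def n_loci(self) -> int:
        return self.effects.size

    @property
    def mean_effect(self) -> float:
        """Realized mean effect size (gamma-bar)."""
        return float(self.effects.mean())

    @property
    def trait_range(self) -> float:
        """Half-width of the attainable trait range, ``sum_i gamma_i``."""
        return float(self.effects.sum())

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write a two-column TSV (locus_id, effect)."""
        with open(path, "w") as fh:
            fh.write("locus_id\teffect\n")
            for i, g in enumerate(self.effects):
                fh.write(f"{i}\t{float(g)!r}\n")

    @classmethod
    def from_tsv(
        cls, path: Union[str, Path], mu_fwd: float = 1e-5, mu_bwd: float = 1e-5
    ) -> "TraitArchitecture":
        rows = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
        return cls(rows[:, 1], mu_fwd=mu_fwd, mu_bwd=mu_bwd)


@dataclass(frozen=True)
class PopulationState:
    """Vector of trait-increasing allele frequencies at one generation."""

    freqs: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValueError("all frequencies must lie in [0, 1]")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")
        object.__setattr__(self, "freqs", p)

    @property
    def n_loci(self) -> int:
        return self.freqs.size


@dataclass(frozen=True)
class SelectionRegime:
    """Gaussian stabilizing selection with a (possibly shifting) optimum.

    The optimum sits at ``z_initial`` for generations before
    ``shift_generation`` and at ``z_final`` from ``shift_generation`` on
    (by convention the shift occurs at t = 0).
    """

    s: float
    z_initial: float
    z_final: float | None = None
    shift_generation: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"selection strength s must be non-negative, got {self.s}")
        if self.z_final is None:
            object.__setattr__(self, "z_final", self.z_initial)

    def optimum_at(self, t):
        """Optimum trait value at generation ``t`` (scalar or array)."""
        return np.where(np.asarray(t) < self.shift_generation, self.z_initial, self.z_final)

    def check_range(self, arch: TraitArchitecture) -> None:
        """Warn when an optimum falls outside the attainable-mean window.

        Convergence of the mean to a stationary state near the optimum
        requires 0 < z0 and z_f < sum_i gamma_i.
        """
        lim = arch.trait_range
        if not 0 < self.z_initial:
            warnings.warn(
                f"initial optimum z0={self.z_initial} is not positive; the mean "
                "may not settle near the optimum",
                stacklevel=2,
            )
        if not self.z_final < lim:
            warnings.warn(
                f"final optimum z_f={self.z_final} exceeds the attainable mean "
                f"range (sum of effects = {lim:.4g})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CumulantTriple:
    """First three cumulants of the genotypic-value distribution."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if self.c2 < 0:
            raise ValueError("genetic variance c2 cannot be negative")


def cumulants_from_freqs(freqs: np.ndarray, effects: np.ndarray):
    """Cumulants (c1, c2, c3) for one or many frequency vectors.

    ``freqs`` may be shape ``(l,)`` or ``(r, l)``; the cumulants are returned
    as scalars or length-``r`` arrays accordingly.
    """
    p = np.asarray(freqs, dtype=float)
    g = np.asarray(effects, dtype=float)
    if p.shape[-1] != g.size:
        raise DimensionMismatchError(
            f"state has {p.shape[-1]} loci but architecture has {g.size}"
        )
    q = 1.0 - p
    pq = p * q
    c1 = (2.0 * p - 1.0) @ g
    c2 = 2.0 * (pq @ g**2)
    c3 = 2.0 * ((pq * (q - p)) @ g**3)
    return c1, c2, c3


def compute_cumulants(state: PopulationState, arch: TraitArchitecture) -> CumulantTriple:
    """Trait mean, genetic variance and third cumulant of the population."""
    c1, c2, c3 = cumulants_from_freqs(state.freqs, arch.effects)
    return CumulantTriple(float(c1), float(max(c2, 0.0)), float(c3))


def fitness(z, regime: SelectionRegime, t: int = 0):
    """Gaussian fitness ``exp(-(s/2)(z - z_opt(t))^2)`` in (0, 1]."""
    d = np.asarray(z, dtype=float) - regime.optimum_at(t)
    return np.exp(-0.5 * regime.s * d * d)


def threshold_effect(mu: float, s: float) -> float:
    """Effect-size threshold ``2 sqrt(2 mu / s)`` separating small from large loci.

    Loci with ``gamma_i`` below this threshold behave as "small-effect" loci:
    in an infinite population their equilibrium frequencies are intermediate
    and their response to an optimum shift is a subtle coherent frequency
    shift rather than a sweep.
    """
    if mu <= 0:
        raise ValueError(f"mutation rate must be positive, got {mu}")
    if s <= 0:
        raise ValueError(f"selection strength must be positive, got {s}")
    return 2.0 * np.sqrt(2.0 * mu / s)
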