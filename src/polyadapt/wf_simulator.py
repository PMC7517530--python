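"""Stochastic Wright-Fisher forward simulator for the polygenic trait.

Each generation applies the deterministic selection + mutation update to
every locus and then resamples 2N gene copies binomially and independently
per locus (free recombination between unlinked loci justifies locus
independence; the loci remain coupled through the trait mean, which each
replicate recomputes from its own frequencies every generation).  The
binomial step realizes the diffusion's drift variance ``p(1-p)/(2N)``
exactly at the conditional level.

Demography is a piecewise-constant schedule of diploid population sizes, so
sudden bottlenecks, recoveries and expansions are a list of epochs.  Fixed
loci stay in the system -- symmetric mutation can re-polymorphize them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .trait_model import (
    PopulationState,
    SelectionRegime,
    TraitArchitecture,
    cumulants_from_freqs,
)
from . import stationary_equilibrium as stat_eq

__all__ = [
    "DemographySchedule",
    "TrajectorySummary",
    "wf_step",
    "simulate",
    "locus_subset_mean",
    "bottleneck_preset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemographySchedule:
    """Ordered epochs of (duration in generations, diploid size N).

    ``origin`` is the generation index at which the schedule starts; with an
    optimum shift at t = 0, a negative origin records pre-shift generations.
    """

    epochs: Tuple[Tuple[int, int], ...]
    origin: int = 0

    def __post_init__(self) -> None:
        ep = tuple((int(d), int(n)) for d, n in self.epochs)
        if not ep:
            raise ValueError("the schedule needs at least one epoch")
        for d, n in ep:
            if d < 1:
                raise ValueError(f"epoch durations must be >= 1 generation, got {d}")
            if n < 2:
                raise ValueError(f"population sizes must be >= 2, got {n}")
        object.__setattr__(self, "epochs", ep)

    @classmethod
    def constant(cls, N: int, duration: int, origin: int = 0) -> "DemographySchedule":
        return cls(((duration, N),), origin=origin)

    @property
    def total_duration(self) -> int:
        return sum(d for d, _ in self.epochs)

    @property
    def boundaries(self) -> np.ndarray:
        """Generation indices of epoch starts plus the final generation."""
        edges = np.concatenate(([0], np.cumsum([d for d, _ in self.epochs])))
        return edges + self.origin

    def size_at(self, t: int) -> int:
        """Diploid size in effect during generation ``t`` (origin-based clock)."""
        off = t - self.origin
        if off < 0 or off >= self.total_duration:
            raise ValueError(f"generation {t} is outside the schedule")
        for d, n in self.epochs:
            if off < d:
                return n
            off -= d
        raise AssertionError("unreachable")

    def sizes_per_generation(self) -> np.ndarray:
        return np.repeat([n for _, n in self.epochs], [d for d, _ in self.epochs])


def bottleneck_preset(equilibrium_generations: int = 20000) -> DemographySchedule:
    """Human-like bottleneck-and-recovery demography.

    After an equilibrium phase at N = 20,000 the population drops suddenly to
    3000 individuals, stays there for 5000 generations, recovers to 20,000
    for 500 generations, and finally expands to 600,000 for the last 100
    generations.  The clock is set so the present is generation 0 and the
    bottleneck starts 5600 generations ago.
    """
    return DemographySchedule(
        epochs=(
            (equilibrium_generations, 20000),
            (5000, 3000),
            (500, 20000),
            (100, 600000),
        ),
        origin=-(equilibrium_generations + 5600),
    )


def _wf_update(
    freqs: np.ndarray,
    effects: np.ndarray,
    s: float,
    mu_fwd: float,
    mu_bwd: float,
    optimum: float,
    N: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation for a (replicates, loci) frequency matrix."""
    q = 1.0 - freqs
    pq = freqs * q
    delta_c1 = (2.0 * freqs - 1.0) @ effects - optimum  # (r,)
    v = (
        -(s * delta_c1)[:, None] * (effects * pq)
        - (0.5 * s * effects**2) * (pq * (q - freqs))
        - mu_fwd * freqs
        + mu_bwd * q
    )
    p_star = np.clip(freqs + v, 0.0, 1.0)
    return rng.binomial(2 * N, p_star) / (2.0 * N)


def wf_step(
    state: PopulationState,
    arch: TraitArchitecture,
    regime: SelectionRegime,
    N: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance a single population by one Wright-Fisher generation.

    Conditional on the current state, the new frequency at each locus has
    mean ``p* = clip(p + velocity)`` and variance ``p*(1-p*)/(2N)``.
    """
    if N < 2:
        raise ValueError(f"population size must be >= 2, got {N}")
    t = state.generation
    new = _wf_update(
        state.freqs[None, :],
        arch.effects,
        regime.s,
        arch.mu_fwd,
        arch.mu_bwd,
        float(regime.optimum_at(t)),
        N,
        rng,
    )[0]
    return PopulationState(new, generation=t + 1)


@dataclass(frozen=True)
class TrajectorySummary:
    """Replicate-averaged trajectory of cumulants and per-locus frequencies."""

    generations: np.ndarray  # (T,)
    mean_delta_c1: np.ndarray  # (T,) average of c1 - current optimum
    mean_c2: np.ndarray
    mean_c3: np.ndarray
    mean_freqs: Optional[np.ndarray]  # (T, l) or None when not recorded
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        T = self.generations.size
        for name in ("mean_delta_c1", "mean_c2", "mean_c3"):
            if getattr(self, name).size != T:
                raise ValueError(f"{name} length does not match generations")
        if self.mean_freqs is not None and self.mean_freqs.shape[0] != T:
            raise ValueError("mean_freqs rows do not match generations")

    # -- writers ---------------------------------------------------------

    def write_trajectory_tsv(self, path: Union[str, Path], extra_columns=None) -> None:
        """TSV of (generation, delta_c1, c2, c3) plus optional named columns."""
        cols = {"delta_c1": self.mean_delta_c1, "c2": self.mean_c2, "c3": self.mean_c3}
        if extra_columns:
            cols.update(extra_columns)
        with open(path, "w") as fh:
            fh.write("generation\t" + "\t".join(cols) + "\n")
            for i, g in enumerate(self.generations):
                fh.write(
                    f"{int(g)}\t" + "\t".join(f"{c[i]:.10g}" for c in cols.values()) + "\n"
                )

    def write_freqs_tsv(self, path: Union[str, Path]) -> None:
        """TSV of replicate-averaged per-locus frequencies (generation x locus)."""
        if self.mean_freqs is None:
            raise ValueError("per-locus frequencies were not recorded")
        l = self.mean_freqs.shape[1]
        with open(path, "w") as fh:
            fh.write("generation\t" + "\t".join(f"locus_{j}" for j in range(l)) + "\n")
            for i, g in enumerate(self.generations):
                fh.write(
                    f"{int(g)}\t"
                    + "\t".join(f"{x:.8g}" for x in self.mean_freqs[i])
                    + "\n"
                )

    def manifest(self) -> dict:
        return {"n_replicates": self.n_replicates, "seed": self.seed}

    def window_mean(self, t_from: int, t_to: int, field: str = "mean_delta_c1") -> float:
        """Time average of a recorded series over generations [t_from, t_to)."""
        mask = (self.generations >= t_from) & (self.generations < t_to)
        if not mask.any():
            raise ValueError(f"no recorded generations in [{t_from}, {t_to})")
        return float(getattr(self, field)[mask].mean())

    def at_generation(self, t: int, field: str = "mean_c2") -> float:
        idx = np.nonzero(self.generations == t)[0]
        if idx.size == 0:
            raise ValueError(f"generation {t} was not recorded")
        return float(getattr(self, field)[idx[0]])


def _stationary_init(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    N: int,
    n_replicates: int,
    rng: np.random.Generator,
    equilibrium_solution=None,
) -> np.ndarray:
    """Per-locus draws from the self-consistent stationary density."""
    if equilibrium_solution is None:
        equilibrium_solution = stat_eq.solve_selfconsistent_equilibrium(arch, regime, N)
    delta = equilibrium_solution.delta_c1_tilde
    alpha = 2.0 * N * regime.s
    beta = 2.0 * N * arch.mu_fwd
    freqs = np.empty((n_replicates, arch.n_loci))
    for j, g in enumerate(arch.effects):
        params = stat_eq.StationaryParams(alpha, beta, g, delta)
        freqs[:, j] = stat_eq.sample_stationary(n_replicates, params, rng)
    return freqs


def simulate(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    demography: DemographySchedule,
    init: Union[PopulationState, str] = "stationary",
    n_replicates: int = 1,
    burn_in: int = 0,
    seed: int = 0,
    record_every: int = 1,
    record_freqs: bool = True,
    equilibrium_solution=None,
    log_every: int = 0,
) -> TrajectorySummary:
    """Run a replicate ensemble across a demographic schedule.

    The ensemble is burned in for ``burn_in`` generations at the first
    epoch's size (with the optimum frozen at its value at the schedule
    origin), then run through the full schedule, recording replicate
    averages of the cumulants (and optionally per-locus mean frequencies)
    every ``record_every`` generations.  ``init`` is either an explicit
    state replicated across the ensemble or ``"stationary"`` for per-locus
    draws from the self-consistent stationary density at the first epoch's
    size.  Fully reproducible for a fixed (seed, n_replicates).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    ss = np.random.SeedSequence(seed)
    init_rng, traj_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    N0 = demography.epochs[0][1]
    if isinstance(init, str):
        if init != "stationary":
            raise ValueError(f"unknown init mode {init!r}")
        freqs = _stationary_init(
            arch, regime, N0, n_replicates, init_rng, equilibrium_solution
        )
    else:
        if init.n_loci != arch.n_loci:
            raise ValueError("initial state and architecture differ in locus count")
        freqs = np.tile(init.freqs, (n_replicates, 1))

    g = arch.effects
    s, mf, mb = regime.s, arch.mu_fwd, arch.mu_bwd
    origin = demography.origin
    z_burn = float(regime.optimum_at(origin))
    for k in range(burn_in):
        freqs = _wf_update(freqs, g, s, mf, mb, z_burn, N0, traj_rng)
        if log_every and (k + 1) % log_every == 0:
            logger.info("burn-in generation %d / %d", k + 1, burn_in)

    total = demography.total_duration
    sizes = demography.sizes_per_generation()
    rec_idx = np.arange(0, total + 1, record_every)
    if rec_idx[-1] != total:
        rec_idx = np.append(rec_idx, total)
    T = rec_idx.size
    gens = origin + rec_idx
    m_dc1 = np.empty(T)
    m_c2 = np.empty(T)
    m_c3 = np.empty(T)
    m_fr = np.empty((T, arch.n_loci)) if record_freqs else None

    rec_set = {int(i): k for k, i in enumerate(rec_idx)}

    def record(off: int) -> None:
        k = rec_set.get(off)
        if k is None:
            return
        t = origin + off
        c1, c2, c3 = cumulants_from_freqs(freqs, g)
        m_dc1[k] = float(np.mean(c1)) - float(regime.optimum_at(t))
        m_c2[k] = float(np.mean(c2))
        m_c3[k] = float(np.mean(c3))
        if m_fr is not None:
            m_fr[k] = freqs.mean(axis=0)

    record(0)
    for off in range(total):
        t = origin + off
        freqs = _wf_update(freqs, g, s, mf, mb, float(regime.optimum_at(t)), int(sizes[off]), traj_rng)
        record(off + 1)
        if log_every and (off + 1) % log_every == 0:
            logger.info("generation %d / %d", off + 1, total)

    return TrajectorySummary(gens, m_dc1, m_c2, m_c3, m_fr, n_replicates, seed)


def locus_subset_mean(
    summary: TrajectorySummary,
    arch: TraitArchitecture,
    effect_center: float,
    tolerance: float,
) -> np.ndarray:
    """Mean-frequency trajectory over loci with effects near a target size.

    Averages the replicate-mean frequencies over all loci with
    ``|gamma_i - effect_center| <= tolerance``.
    """
    if summary.mean_freqs is None:
        raise ValueError("per-locus frequencies were not recorded in this summary")
    mask = np.abs(arch.effects - effect_center) <= tolerance
    if not mask.any():
        raise ValueError(
            f"no locus has an effect within {tolerance} of {effect_center}"
        )
    return summary.mean_freqs[:, mask].mean(axis=1)
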