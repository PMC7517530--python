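"""Stationary allele-frequency distribution under drift, mutation and selection.

For a locus of effect ``gamma`` embedded in a polygenic trait whose mean sits
at a quasi-equilibrium deviation ``dc1~`` from the optimum, diffusion theory
gives the stationary density of the trait-increasing allele frequency

``f(p) = C p^(2b-1) (1-p)^(2b-1) exp(-2 a g dc1~ p - a g^2 p (1-p))``

with scaled parameters ``a = 2 N s`` and ``b = 2 N mu``.  This is Wright's
stationary distribution with the selection potential of the polygenic model:
a directional term tilting the density toward + alleles when ``dc1~ < 0``,
and an underdominant-like stabilizing term disfavoring intermediate
frequencies.  For ``b < 1/2`` (realistic mutation rates in moderately sized
populations) the density is U-shaped, diverging at both boundaries -- the
finite-population equilibrium is drastically different from the
intermediate-frequency equilibria of the deterministic model.

The normalization constant is always computed by adaptive quadrature under
the substitution ``p = sin^2(theta)``, which removes the integrable endpoint
singularities.  A linearized closed form in terms of the beta function,

``1/C ~= B(2b, 2b) (1 - a g dc1~ - a g^2 b / (4 b + 1))``,

is exposed separately as an approximation and never used as the normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np
from scipy import integrate, special

from .trait_model import SelectionRegime, TraitArchitecture
from .deterministic_theory import quasi_equilibrium_deviation

__all__ = [
    "StationaryParams",
    "EquilibriumSolution",
    "ApproximationRangeError",
    "ConvergenceError",
    "stationary_density",
    "stationary_cdf",
    "normalization_constant",
    "normalization_approx",
    "stationary_moments",
    "sample_stationary",
    "solve_selfconsistent_equilibrium",
]


class ApproximationRangeError(ValueError):
    """The linearized normalization constant is invalid for these parameters."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge."""


@dataclass(frozen=True)
class StationaryParams:
    """Scaled parameters of the single-locus stationary density."""

    alpha: float  # 2 N s
    beta: float  # 2 N mu
    gamma: float  # locus effect size
    delta_c1_tilde: float = 0.0  # quasi-equilibrium mean deviation, held fixed

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"alpha and beta must be positive, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    @classmethod
    def from_rates(
        cls, N: int, s: float, mu: float, gamma: float, delta_c1_tilde: float = 0.0
    ) -> "StationaryParams":
        return cls(2.0 * N * s, 2.0 * N * mu, gamma, delta_c1_tilde)


def _log_kernel(p, params: StationaryParams):
    """Log of the unnormalized density at interior points."""
    q = 1.0 - p
    return (
        (2.0 * params.beta - 1.0) * (np.log(p) + np.log(q))
        - 2.0 * params.alpha * params.gamma * params.delta_c1_tilde * p
        - params.alpha * params.gamma**2 * p * q
    )


def _theta_integrand(params: StationaryParams, weight=None):
    """Integrand of int_0^1 kernel(p) w(p) dp after p = sin^2(theta).

    The beta-kernel factor becomes 2 (sin t)^(4b-1) (cos t)^(4b-1), which is
    integrable (and smooth for b >= 1/4) on [0, pi/2].
    """
    b4 = 4.0 * params.beta - 1.0
    a, g, d = params.alpha, params.gamma, params.delta_c1_tilde

    def f(theta):
        st, ct = np.sin(theta), np.cos(theta)
        p = st * st
        pq = p * (1.0 - p)
        val = 2.0 * (st * ct) ** b4 * np.exp(-2.0 * a * g * d * p - a * g * g * pq)
        if weight is not None:
            val = val * weight(p)
        return val

    return f


def _quad(params: StationaryParams, weight=None) -> float:
    val, _ = integrate.quad(
        _theta_integrand(params, weight),
        0.0,
        np.pi / 2.0,
        epsabs=1e-11,
        epsrel=1e-9,
        limit=200,
    )
    return val


def normalization_constant(params: StationaryParams) -> float:
    """Exact normalization constant C by adaptive quadrature."""
    z = _quad(params)
    if not np.isfinite(z) or z <= 0:
        raise RuntimeError(f"quadrature for the normalization failed (integral={z})")
    return 1.0 / z


def stationary_density(p, params: StationaryParams):
    """Normalized stationary density f(p) on the open interval (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("the density is defined on the open interval (0, 1)")
    return normalization_constant(params) * np.exp(_log_kernel(p, params))


def stationary_cdf(p, params: StationaryParams):
    """CDF of the stationary density, by quadrature on [0, p]."""
    C = normalization_constant(params)
    f = _theta_integrand(params)
    scalar = np.isscalar(p)
    ps = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(ps < 0.0) or np.any(ps > 1.0):
        raise ValueError("the CDF argument must lie in [0, 1]")
    out = np.empty_like(ps)
    for i, pi in enumerate(ps):
        theta = np.arcsin(np.sqrt(pi))
        val, _ = integrate.quad(f, 0.0, theta, epsabs=1e-11, epsrel=1e-9, limit=200)
        out[i] = C * val
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def normalization_approx(params: StationaryParams) -> float:
    """Linearized (beta-function) approximation to the normalization constant.

    Accurate when ``a g |dc1~|`` and ``a g^2`` are small; raises
    :class:`ApproximationRangeError` when the linearization bracket is not
    positive, signalling that the expansion has broken down.
    """
    b = params.beta
    bracket = (
        1.0
        - params.alpha * params.gamma * params.delta_c1_tilde
        - params.alpha * params.gamma**2 * b / (4.0 * b + 1.0)
    )
    if bracket <= 0.0:
        raise ApproximationRangeError(
            f"linearized normalization invalid: bracket={bracket:.4g} <= 0"
        )
    return 1.0 / (special.beta(2.0 * b, 2.0 * b) * bracket)


def stationary_moments(params: StationaryParams):
    """Quadrature moments (E[p], E[pq], E[pq(q-p)]) of the stationary density."""
    z = _quad(params)
    if not np.isfinite(z) or z <= 0:
        raise RuntimeError(f"quadrature for the normalization failed (integral={z})")
    e_p = _quad(params, lambda p: p) / z
    e_pq = _quad(params, lambda p: p * (1.0 - p)) / z
    e_pq_qmp = _quad(params, lambda p: p * (1.0 - p) * (1.0 - 2.0 * p)) / z
    return e_p, e_pq, e_pq_qmp


def sample_stationary(
    n: int,
    params: StationaryParams,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Draw n i.i.d. frequencies from the stationary density.

    Rejection sampling with a symmetric Beta(2b, 2b) proposal: the
    non-beta factor ``exp(-2 a g d p - a g^2 pq)`` is bounded above by
    ``exp(max(0, -2 a g d))`` on [0, 1], giving an exact envelope.
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b, g, d = params.alpha, params.beta, params.gamma, params.delta_c1_tilde
    log_env = max(0.0, -2.0 * a * g * d)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 256)
        prop = rng.beta(2.0 * b, 2.0 * b, size=m)
        # guard against underflow to exactly 0/1 in the beta sampler
        prop = np.clip(prop, 1e-300, 1.0 - 1e-16)
        log_acc = -2.0 * a * g * d * prop - a * g * g * prop * (1.0 - prop) - log_env
        keep = prop[np.log(rng.random(m)) < log_acc]
        k = min(keep.size, n - filled)
        out[filled : filled + k] = keep[:k]
        filled += k
    return out


# ---------------------------------------------------------------------------
# Fast fixed-grid moments (vectorized over loci) for the self-consistent solve
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def _gl_grid(n_nodes: int = 600):
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.25 * np.pi * (x + 1.0)
    w = w * 0.25 * np.pi
    return theta, w


def locus_moments(
    gammas: np.ndarray, alpha: float, beta: float, delta_c1_tilde: float, n_nodes: int = 600
):
    """Stationary moments (E[p], E[pq], E[pq(q-p)]) for many loci at once.

    Gauss-Legendre quadrature on the theta grid, vectorized over effect
    sizes.  Requires ``beta >= 1/4`` so the transformed integrand is
    bounded; callers fall back to adaptive quadrature otherwise.
    """
    if beta < 0.25:
        g = np.asarray(gammas, dtype=float)
        out = np.array(
            [
                stationary_moments(StationaryParams(alpha, beta, gi, delta_c1_tilde))
                for gi in g
            ]
        )
        return out[:, 0], out[:, 1], out[:, 2]
    theta, w = _gl_grid(n_nodes)
    st, ct = np.sin(theta), np.cos(theta)
    p = st * st
    pq = p * (1.0 - p)
    base = 2.0 * (st * ct) ** (4.0 * beta - 1.0)  # (nodes,)
    g = np.asarray(gammas, dtype=float)[:, None]
    log_sel = -2.0 * alpha * g * delta_c1_tilde * p - alpha * g * g * pq  # (l, nodes)
    kern = base * np.exp(log_sel)
    z = kern @ w
    e_p = (kern * p) @ w / z
    e_pq = (kern * pq) @ w / z
    e_pq_qmp = (kern * (pq * (1.0 - 2.0 * p))) @ w / z
    return e_p, e_pq, e_pq_qmp


@dataclass(frozen=True)
class EquilibriumSolution:
    """Self-consistent stationary equilibrium of the full trait."""

    delta_c1_tilde: float
    c2: float
    c3: float
    c1: float
    n_iterations: int


def solve_selfconsistent_equilibrium(
    arch: TraitArchitecture,
    regime: SelectionRegime,
    N: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
) -> EquilibriumSolution:
    """Solve the mean-field fixed point coupling the density to the cumulants.

    The quasi-equilibrium mean deviation enters the stationary density of
    every locus, while the density's moments determine the equilibrium
    variance and skewness that in turn fix the mean deviation.  Damped
    fixed-point iteration:

        dc1~  ->  per-locus moments  ->  (c2~, c3~)  ->  dc1~'

    until ``|dc1~' - dc1~| < tol``.
    """
    if N < 2:
        raise ValueError(f"population size must be at least 2, got {N}")
    if arch.mu_fwd != arch.mu_bwd:
        raise ValueError("the stationary theory assumes symmetric mutation (mu = nu)")
    mu = arch.mu_fwd
    alpha = 2.0 * N * regime.s
    beta = 2.0 * N * mu
    if beta <= 0:
        raise ValueError("the stationary density requires mu > 0")
    g = arch.effects
    delta = 0.0
    c2 = c3 = c1 = 0.0
    for it in range(1, max_iter + 1):
        e_p, e_pq, e_pq_qmp = locus_moments(g, alpha, beta, delta)
        c1 = float((2.0 * e_p - 1.0) @ g)
        c2 = float(2.0 * (e_pq @ g**2))
        c3 = float(2.0 * (e_pq_qmp @ g**3))
        new = quasi_equilibrium_deviation(c2, c3, regime, mu)
        step = new - delta
        delta = delta + damping * step
        if abs(step) < tol:
            # polish with undamped iterations so the returned deviation is a
            # fixed point of the map to well below the requested tolerance
            for jt in range(20):
                e_p, e_pq, e_pq_qmp = locus_moments(g, alpha, beta, delta)
                c1 = float((2.0 * e_p - 1.0) @ g)
                c2 = float(2.0 * (e_pq @ g**2))
                c3 = float(2.0 * (e_pq_qmp @ g**3))
                new = quasi_equilibrium_deviation(c2, c3, regime, mu)
                done = abs(new - delta) < 1e-13
                delta = new
                if done:
                    break
            return EquilibriumSolution(delta, c2, c3, c1, it + jt + 1)
    raise ConvergenceError(
        f"self-consistent equilibrium did not converge in {max_iter} iterations "
        f"(last step {step:.3e})"
    )
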