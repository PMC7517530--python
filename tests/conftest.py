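import numpy as np
import pytest

from polyadapt import SelectionRegime, TraitArchitecture


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_arch():
    """Three loci with distinct effects, symmetric mutation."""
    return TraitArchitecture(np.array([0.01, 0.02, 0.005]), 1e-5, 1e-5)


@pytest.fixture
def standard_regime():
    """Human-calibrated stabilizing selection about z0 = 0.2."""
    return SelectionRegime(s=0.1, z_initial=0.2)


def hwe_cumulants(p, gamma):
    """Exact cumulants of the genotypic value by brute-force enumeration.

    Enumerates all diploid genotype combinations across loci under
    Hardy-Weinberg and linkage equilibrium; a locus genotype with g copies
    of the + allele has value (g - 1) * gamma_i and HWE weight
    C(2, g) p^g q^(2-g).  Independent oracle for the cumulant formulas.
    """
    import itertools
    from math import comb

    p = np.atleast_1d(np.asarray(p, float))
    gamma = np.atleast_1d(np.asarray(gamma, float))
    values = []
    weights = []
    for combo in itertools.product((0, 1, 2), repeat=len(p)):
        w = 1.0
        z = 0.0
        for g, pi, gi in zip(combo, p, gamma):
            w *= comb(2, g) * pi**g * (1 - pi) ** (2 - g)
            z += (g - 1) * gi
        values.append(z)
        weights.append(w)
    values = np.array(values)
    weights = np.array(weights)
    mean = np.sum(weights * values)
    var = np.sum(weights * (values - mean) ** 2)
    third = np.sum(weights * (values - mean) ** 3)
    return mean, var, third
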