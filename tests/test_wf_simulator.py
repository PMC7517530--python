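"""Wright-Fisher simulator: sampling contracts, drift oracles, demography."""

import numpy as np
import pytest

from polyadapt import (
    DemographySchedule,
    PopulationState,
    SelectionRegime,
    StationaryParams,
    TraitArchitecture,
    bottleneck_preset,
    integrate_deterministic,
    locus_subset_mean,
    simulate,
    stationary_cdf,
    wf_step,
)
from polyadapt.wf_simulator import _wf_update


class TestDemographySchedule:
    def test_validation(self):
        with pytest.raises(ValueError):
            DemographySchedule(epochs=())
        with pytest.raises(ValueError):
            DemographySchedule(epochs=((0, 100),))
        with pytest.raises(ValueError):
            DemographySchedule(epochs=((10, 1),))

    def test_size_lookup(self):
        d = DemographySchedule(epochs=((10, 100), (5, 50)), origin=-15)
        assert d.total_duration == 15
        assert d.size_at(-15) == 100
        assert d.size_at(-6) == 100
        assert d.size_at(-5) == 50
        assert d.size_at(-1) == 50
        with pytest.raises(ValueError):
            d.size_at(0)
        np.testing.assert_array_equal(d.boundaries, [-15, -5, 0])

    def test_bottleneck_preset_matches_demographic_history(self):
        """Stationary 2e4, drop to 3000 for 5000 gens, recovery, expansion."""
        d = bottleneck_preset()
        assert d.epochs == ((20000, 20000), (5000, 3000), (500, 20000), (100, 600000))
        assert d.total_duration == 25600
        assert d.origin == -25600
        # post-equilibrium span: bottleneck start 5600 generations ago
        assert d.boundaries[1] == -5600
        assert d.boundaries[2] == -600  # recovery
        assert d.boundaries[3] == -100  # expansion
        assert d.size_at(-1) == 600000

    def test_bottleneck_preset_configurable_equilibrium(self):
        d = bottleneck_preset(equilibrium_generations=1000)
        assert d.total_duration == 6600 and d.boundaries[1] == -5600


class TestWfStep:
    def test_absorbing_boundary_without_mutation(self):
        arch = TraitArchitecture(np.array([0.01, 0.02]), 0.0, 0.0)
        reg = SelectionRegime(s=0.1, z_initial=0.2)
        state = PopulationState(np.array([0.0, 1.0]))
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = wf_step(state, arch, reg, 100, rng)
        np.testing.assert_array_equal(state.freqs, [0.0, 1.0])
        assert state.generation == 20

    def test_conditional_moment_contract(self):
        """One-generation ensemble mean is p* and variance p*(1-p*)/(2N)."""
        g, s, N, p0 = 0.01, 0.1, 200, 0.4
        R = 100_000
        rng = np.random.default_rng(1)
        arch_eff = np.array([g])
        new = _wf_update(np.full((R, 1), p0), arch_eff, s, 1e-5, 1e-5, 0.2, N, rng)[:, 0]
        # deterministic post-selection frequency, recomputed independently
        q0 = 1 - p0
        dc1 = g * (2 * p0 - 1) - 0.2
        p_star = p0 + (-s * g * p0 * q0 * dc1 - 0.5 * s * g**2 * p0 * q0 * (q0 - p0)
                       - 1e-5 * p0 + 1e-5 * q0)
        se_mean = np.sqrt(p_star * (1 - p_star) / (2 * N)) / np.sqrt(R)
        assert new.mean() == pytest.approx(p_star, abs=3 * se_mean)
        var = p_star * (1 - p_star) / (2 * N)
        se_var = var * np.sqrt(2.0 / R)  # approximate SE of a variance estimate
        assert new.var() == pytest.approx(var, abs=3 * se_var)

    def test_neutral_heterozygosity_decay(self):
        """Without selection or mutation, E[pq] decays by (1 - 1/2N) per
        generation -- the classical neutral drift oracle."""
        N, t = 50, 20
        l, R = 2000, 50
        arch = TraitArchitecture(np.ones(l), 0.0, 0.0)
        reg = SelectionRegime(s=0.0, z_initial=0.0)
        demog = DemographySchedule.constant(N, t)
        summary = simulate(
            arch, reg, demog,
            init=PopulationState(np.full(l, 0.5)),
            n_replicates=R, seed=2, record_freqs=False,
        )
        # c2 = 2 sum(pq) for unit effects -> mean pq = c2 / (2 l)
        mean_pq = summary.mean_c2[-1] / (2 * l)
        expected = 0.25 * (1 - 1 / (2 * N)) ** t
        # binomial-ish MC error on the pq average over l*R trajectories
        se = 0.25 / np.sqrt(l * R)
        assert mean_pq == pytest.approx(expected, abs=3 * se)

    def test_small_population_size_rejected(self):
        arch = TraitArchitecture(np.array([0.01]), 0.0, 0.0)
        reg = SelectionRegime(s=0.1, z_initial=0.0)
        with pytest.raises(ValueError):
            wf_step(PopulationState(np.array([0.5])), arch, reg, 1, np.random.default_rng(0))


class TestSimulate:
    def test_deterministic_limit_at_huge_population(self):
        """A single replicate at N = 1e8 tracks the deterministic flow."""
        rng = np.random.default_rng(5)
        arch = TraitArchitecture(rng.exponential(0.01, 50), 1e-5, 1e-5)
        p0 = rng.uniform(0.3, 0.7, 50)
        c1_0 = float((2 * p0 - 1) @ arch.effects)
        reg = SelectionRegime(s=0.1, z_initial=c1_0, z_final=c1_0 + 0.3)
        demog = DemographySchedule.constant(1_000_000_000, 200)
        summary = simulate(
            arch, reg, demog, init=PopulationState(p0), n_replicates=1, seed=6,
        )
        det = integrate_deterministic(PopulationState(p0), arch, reg, 200)
        np.testing.assert_allclose(summary.mean_delta_c1, det.delta_c1, atol=1e-3)
        np.testing.assert_allclose(summary.mean_freqs, det.freqs, atol=1e-3)

    def test_reproducibility_and_seed_sensitivity(self):
        arch = TraitArchitecture(np.full(10, 0.01), 1e-5, 1e-5)
        reg = SelectionRegime(s=0.1, z_initial=0.05)
        demog = DemographySchedule.constant(500, 50)
        kw = dict(init=PopulationState(np.full(10, 0.5)), n_replicates=4, burn_in=10)
        a = simulate(arch, reg, demog, seed=7, **kw)
        b = simulate(arch, reg, demog, seed=7, **kw)
        c = simulate(arch, reg, demog, seed=8, **kw)
        np.testing.assert_array_equal(a.mean_freqs, b.mean_freqs)
        np.testing.assert_array_equal(a.mean_c2, b.mean_c2)
        assert not np.array_equal(a.mean_freqs, c.mean_freqs)

    def test_stationarity_of_long_equilibrium_run(self):
        """With constant N and no shift, first- and second-half time averages
        of the variance agree within noise (block-corrected)."""
        arch = TraitArchitecture(np.full(50, 0.01), 5e-4, 5e-4)
        reg = SelectionRegime(s=0.1, z_initial=0.05)
        N, span = 500, 4000
        summary = simulate(
            arch, reg, DemographySchedule.constant(N, span),
            init="stationary", n_replicates=8, burn_in=2000, seed=9,
            record_freqs=False,
        )
        halves = np.array_split(summary.mean_c2[1:], 2)
        # blocks longer than the ~2N-generation correlation time
        blocks = [np.array_split(h, 4) for h in halves]
        bm = [np.array([b.mean() for b in h]) for h in blocks]
        diff = abs(bm[0].mean() - bm[1].mean())
        pooled_se = np.sqrt(bm[0].var(ddof=1) / 4 + bm[1].var(ddof=1) / 4)
        assert diff < 2 * pooled_se

    def test_occupancy_matches_stationary_density(self):
        """Long-run occupancy of a locus matches the diffusion stationary
        CDF (KS distance < 0.05): the diffusion-approximation quality check."""
        # symmetric setting (z0 = 0) so the fixed-tilt density with dc1~ = 0
        # applies; many loci keep the mean-field deviation small
        l, N, s, mu, g = 50, 500, 0.1, 2e-4, 0.02
        arch = TraitArchitecture(np.full(l, g), mu, mu)
        reg = SelectionRegime(s=s, z_initial=0.0)
        span = 20 * 2 * N
        # a single replicate keeps the occupancy interpretation exact
        summary = simulate(
            arch, reg, DemographySchedule.constant(N, span),
            init="stationary", n_replicates=1, burn_in=2 * N, seed=10,
            record_every=25, record_freqs=True,
        )
        pool = summary.mean_freqs.ravel()
        pool = pool[(pool > 0) & (pool < 1)]
        params = StationaryParams.from_rates(N, s, mu, g, 0.0)
        grid = np.linspace(0.02, 0.98, 49)
        theory = stationary_cdf(grid, params)
        emp = np.searchsorted(np.sort(pool), grid, side="right") / pool.size
        assert np.max(np.abs(emp - theory)) < 0.05

    def test_alignment_is_strongest_at_intermediate_frequencies(self):
        """After a shift, loci starting at intermediate frequencies align with
        the optimum more often than loci starting near the boundaries."""
        rng = np.random.default_rng(11)
        l = 400
        arch = TraitArchitecture(np.full(l, 0.01), 1e-5, 1e-5)
        # explicit starting frequencies spanning intermediate and extreme
        # bands, shared by all replicates, so loci are classified by their
        # true frequency at the shift
        p0 = np.concatenate([
            rng.uniform(0.3, 0.7, 150),
            rng.uniform(0.02, 0.08, 75),
            rng.uniform(0.92, 0.98, 75),
            rng.uniform(0.1, 0.9, 100),
        ])
        c1_0 = float((2 * p0 - 1) @ arch.effects)
        reg = SelectionRegime(s=0.1, z_initial=c1_0, z_final=c1_0 + 0.3)
        N = 5000
        demog = DemographySchedule.constant(N, 2000)
        summary = simulate(
            arch, reg, demog, init=PopulationState(p0), n_replicates=40,
            seed=12, record_every=100, record_freqs=True,
        )
        dp = summary.mean_freqs[-1] - p0
        mid = (p0 > 0.3) & (p0 < 0.7)
        extreme = (p0 < 0.1) | (p0 > 0.9)
        assert mid.sum() > 10 and extreme.sum() > 10
        frac_mid = np.mean(dp[mid] > 0)
        frac_ext = np.mean(dp[extreme] > 0)
        assert frac_mid > frac_ext

    def test_config_errors(self):
        arch = TraitArchitecture(np.array([0.01]), 1e-5, 1e-5)
        reg = SelectionRegime(s=0.1, z_initial=0.0)
        demog = DemographySchedule.constant(100, 10)
        with pytest.raises(ValueError):
            simulate(arch, reg, demog, init="bogus", seed=0)
        with pytest.raises(ValueError):
            simulate(arch, reg, demog, init=PopulationState(np.array([0.5, 0.5])), seed=0)
        with pytest.raises(ValueError):
            simulate(arch, reg, demog, init=PopulationState(np.array([0.5])), n_replicates=0)


class TestTrajectorySummary:
    @pytest.fixture()
    def summary(self):
        arch = TraitArchitecture(np.array([0.01, 0.02, 0.1]), 1e-5, 1e-5)
        reg = SelectionRegime(s=0.1, z_initial=0.05)
        return (
            simulate(
                arch, reg, DemographySchedule.constant(200, 20),
                init=PopulationState(np.array([0.5, 0.4, 0.6])),
                n_replicates=3, seed=13,
            ),
            arch,
        )

    def test_locus_subset_mean(self, summary):
        s, arch = summary
        window = locus_subset_mean(s, arch, 0.015, 0.006)  # loci 0.01 and 0.02
        np.testing.assert_allclose(window, s.mean_freqs[:, :2].mean(axis=1))
        everything = locus_subset_mean(s, arch, 0.0, np.inf)
        np.testing.assert_allclose(everything, s.mean_freqs.mean(axis=1))
        with pytest.raises(ValueError):
            locus_subset_mean(s, arch, 5.0, 0.1)

    def test_writers(self, summary, tmp_path):
        s, arch = summary
        s.write_trajectory_tsv(tmp_path / "traj.tsv")
        s.write_freqs_tsv(tmp_path / "freqs.tsv")
        rows = (tmp_path / "traj.tsv").read_text().strip().split("\n")
        assert rows[0] == "generation\tdelta_c1\tc2\tc3"
        assert len(rows) == s.generations.size + 1
        frows = (tmp_path / "freqs.tsv").read_text().strip().split("\n")
        assert frows[0].startswith("generation\tlocus_0")

    def test_window_and_point_accessors(self, summary):
        s, _ = summary
        assert s.window_mean(0, 10, "mean_c2") == pytest.approx(
            s.mean_c2[(s.generations >= 0) & (s.generations < 10)].mean()
        )
        assert s.at_generation(5, "mean_c2") == s.mean_c2[5]
        with pytest.raises(ValueError):
            s.window_mean(100, 200)
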