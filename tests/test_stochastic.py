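"""Discrete-molecule simulation: propensities, SSA, hybrid solver, analysis."""

import numpy as np
import pytest
from scipy import stats

from xapswitch import (CellGeometry, CircuitVariant, ReactionNetwork,
                       adaptation_times, build_network, find_fixed_points,
                       run_ensemble, simulate_direct, simulate_hybrid,
                       split_bimodal, table1)
from xapswitch.stochastic import mean_field_residual


@pytest.fixture(scope="module")
def net(t1, geom):
    return build_network(t1, geom)


class TestNetwork:
    def test_zero_counts_leave_only_source_channels(self, net):
        a = net.propensities((0, 0, 0))
        # transcription (leak) and Nup influx are the only live channels
        assert a[0] > 0 and a[7] > 0
        assert np.all(a[[1, 2, 3, 4, 5, 6, 8]] == 0)

    def test_no_protein_silences_transporter_channels(self, net):
        a = net.propensities((5, 0, 1000))
        assert np.all(a[[4, 5, 6]] == 0)

    def test_propensities_reject_negative_counts(self, net):
        with pytest.raises(ValueError):
            net.propensities((-1, 0, 0))

    def test_mean_field_consistency(self, t1, geom, rng):
        # S^T a(Omega y) == Omega rhs(y) exactly, for the wild type and
        # the ablation variants
        for v in (CircuitVariant(), CircuitVariant(xapA_removed=True),
                  CircuitVariant(xapB_removed=True)):
            network = build_network(t1, geom, v)
            for _ in range(20):
                y = 10 ** rng.uniform(-4, 2, size=3)
                assert mean_field_residual(network, y) < 1e-10

    def test_kernel_activity_matches_reference_rate_law(self, t1, geom):
        from xapswitch._kernels import p_active_kernel
        from xapswitch.variants import apply_variant

        xs = np.geomspace(1e-4, 1e5, 40)
        for v in (CircuitVariant(), CircuitVariant(promoter_sites=1),
                  CircuitVariant(inducer_sites_per_TF=1),
                  CircuitVariant(active_policy="any_xapr_bound")):
            network = build_network(t1, geom, v)
            laws = apply_variant(v, t1)
            got = np.array([p_active_kernel(x, network.theta) for x in xs])
            assert np.allclose(got, laws.p_active(xs), rtol=1e-13)

    def test_burst_rates_preserve_drift(self, t1, geom):
        plain = build_network(t1, geom)
        bursty = build_network(t1, geom, bursts=True, burst_m=4.0, burst_p=3.0)
        y = np.array([1e-4, 1e-2, 50.0])
        c = y * geom.omega
        assert np.allclose(bursty.macroscopic_drift(c),
                           plain.macroscopic_drift(c), rtol=1e-12)
        with pytest.raises(ValueError):
            build_network(t1, geom, bursts=False, burst_m=4.0)


class TestDirectSSA:
    def test_birth_death_is_poisson(self):
        # stationary law of a birth-death process is Poisson(a/gamma)
        bd = ReactionNetwork.birth_death(5.0, 1.0)
        finals = [simulate_direct(bd, (0, 0, 0), 30.0, seed=1000 + i).final[0]
                  for i in range(1500)]
        finals = np.asarray(finals)
        assert finals.mean() == pytest.approx(5.0, abs=4 * np.sqrt(5 / 1500))
        kmax = 13
        obs = np.bincount(np.minimum(finals, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 5.0)
        probs = np.append(pmf, 1 - pmf.sum())
        chi2 = stats.chisquare(obs, probs * len(finals))
        assert chi2.pvalue > 1e-3

    def test_identical_seed_identical_path(self, net):
        a = simulate_direct(net, (0, 0, 0), 5.0, seed=42)
        b = simulate_direct(net, (0, 0, 0), 5.0, seed=42)
        c = simulate_direct(net, (0, 0, 0), 5.0, seed=43)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.final, b.final)
        assert not np.array_equal(a.counts, c.counts)

    def test_zero_propensity_network_is_frozen(self):
        silent = ReactionNetwork.birth_death(0.0, 0.0)
        tr = simulate_direct(silent, (0, 3, 0), 100.0, seed=7)
        assert np.array_equal(tr.final, [0, 3, 0])
        assert tr.n_events == 0

    def test_event_budget_overflow_raises(self, t1, geom):
        # the induced state fires ~1e7 xanthosine events per time unit:
        # infeasible for the direct method, by design
        p25 = t1.with_(c_a=25.0)
        network = build_network(p25, geom)
        upper = find_fixed_points(p25)[-1]
        c0 = geom.counts_from_state(upper.state.as_array())
        with pytest.raises(RuntimeError, match="hybrid"):
            simulate_direct(network, c0, 10.0, seed=1, max_events=200_000)


class TestHybrid:
    def test_matches_direct_when_nothing_leaps(self):
        # low-copy system: the partition never selects a channel, so the
        # hybrid path must sample the same stationary law as direct SSA
        bd = ReactionNetwork.birth_death(20.0, 1.0)
        fd = [simulate_direct(bd, (0, 0, 0), 25.0, seed=i).final[0]
              for i in range(800)]
        fh = [simulate_hybrid(bd, (0, 0, 0), 25.0, seed=10_000 + i).final[0]
              for i in range(800)]
        ks = stats.ks_2samp(fd, fh)
        assert ks.pvalue > 0.01

    def test_matches_direct_with_active_leaping(self):
        # high birth rate crosses the leap threshold while the copy number
        # stays below the count threshold for the death channel
        bd = ReactionNetwork.birth_death(2000.0, 50.0)
        fd = [simulate_direct(bd, (0, 0, 0), 0.4, seed=i).final[0]
              for i in range(600)]
        fh = [simulate_hybrid(bd, (0, 0, 0), 0.4, seed=10_000 + i).final[0]
              for i in range(600)]
        ks = stats.ks_2samp(fd, fh)
        assert ks.pvalue > 0.01

    def test_reaches_induced_state_from_zero(self, t1, geom):
        # at c_a = 25 the only attractor is the induced state with
        # xanthosine copy numbers of order 1e7
        p25 = t1.with_(c_a=25.0)
        network = build_network(p25, geom)
        upper = find_fixed_points(p25)[-1]
        tr = simulate_hybrid(network, (0, 0, 0), 250.0, seed=5)
        assert 1e6 < tr.final[2] < 1e8
        assert 0.5 * upper.state.p_a * geom.omega < tr.final[1] \
            < 2.0 * upper.state.p_a * geom.omega

    def test_constitutive_limit_mrna_is_poisson(self, geom):
        # freezing p_active removes all feedback on transcription; the
        # stationary mRNA marginal is Poisson(rho_m p_active Omega/gamma_mp)
        small = CellGeometry(volume_L=1e-18)
        # translation and non-specific uptake are switched off so the
        # mRNA marginal is an isolated birth-death process
        params = table1(rho_m=1.0, rho_p=1e-9, k_eta=1e-9)
        network = build_network(params, small, constitutive_p_active=0.5)
        mean = params.rho_m * 0.5 * small.omega / params.gamma_mp
        finals = np.array([
            simulate_direct(network, (0, 0, 0), 3.0, seed=i).final[0]
            for i in range(1200)])
        assert finals.mean() == pytest.approx(
            mean, abs=4 * np.sqrt(mean / 1200))
        kmax = 7
        obs = np.bincount(np.minimum(finals, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), mean)
        probs = np.append(pmf, 1 - pmf.sum())
        assert stats.chisquare(obs, probs * len(finals)).pvalue > 1e-3

    def test_bursts_raise_mrna_fano_factor(self, geom):
        small = CellGeometry(volume_L=1e-18)
        params = table1(rho_m=10.0, rho_p=1e-9, k_eta=1e-9)
        plain = build_network(params, small, constitutive_p_active=0.5)
        bursty = build_network(params, small, constitutive_p_active=0.5,
                               bursts=True, burst_m=5.0)
        fp = np.array([simulate_direct(plain, (0, 0, 0), 3.0, seed=i).final[0]
                       for i in range(800)])
        fb = np.array([simulate_direct(bursty, (0, 0, 0), 3.0, seed=i).final[0]
                       for i in range(800)])
        fano_p = fp.var(ddof=1) / fp.mean()
        fano_b = fb.var(ddof=1) / fb.mean()
        assert 0.7 < fano_p < 1.4          # Poisson-like without bursts
        assert fano_b > 2.0                # geometric bursts widen the law
        # burst mode preserves the mean expression level
        assert fb.mean() == pytest.approx(fp.mean(), rel=0.15)


class TestEnsembles:
    def test_reproducible_and_bookkept(self, net):
        e1 = run_ensemble(net, (0, 0, 0), 5.0, 8, base_seed=3, algorithm="direct")
        e2 = run_ensemble(net, (0, 0, 0), 5.0, 8, base_seed=3, algorithm="direct")
        assert np.array_equal(e1.endpoints, e2.endpoints)
        assert len(e1.seeds) == e1.n_runs == 8
        assert e1.failures == []
        with pytest.raises(ValueError):
            run_ensemble(net, (0, 0, 0), 5.0, 0, base_seed=3)


class TestModeSplit:
    def test_recovers_well_separated_mixture(self, rng):
        x = np.concatenate([rng.normal(5, 1, 5000), rng.normal(500, 50, 5000)])
        sp = split_bimodal(x)
        assert sp.n_modes == 2
        assert sp.means[0] == pytest.approx(5.0, rel=0.05)
        assert sp.means[1] == pytest.approx(500.0, rel=0.05)
        # binomial error on the 50/50 weights at n = 1e4
        assert abs(sp.weights[0] - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_single_gaussian_is_one_mode(self, rng):
        sp = split_bimodal(rng.normal(100, 10, 5000))
        assert sp.n_modes == 1 and sp.split_point is None

    def test_constant_sample_degenerates(self):
        sp = split_bimodal(np.full(50, 7.0))
        assert sp.n_modes == 1 and sp.means[0] == 7.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            split_bimodal([])


class TestAdaptationTimes:
    def test_zero_threshold_crosses_immediately(self, net):
        ens = run_ensemble(net, (0, 0, 0), 2.0, 5, base_seed=1,
                           algorithm="direct", record_trajectories=True)
        at = adaptation_times(ens, reference_protein_count=100, threshold=0.0)
        assert np.all(at.times == 0.0)
        assert at.n_censored == 0

    def test_censored_runs_are_counted_not_dropped(self, net):
        # uninduced runs never reach hundreds of proteins in 2 time units
        ens = run_ensemble(net, (0, 0, 0), 2.0, 5, base_seed=1,
                           algorithm="direct", record_trajectories=True)
        at = adaptation_times(ens, reference_protein_count=500, threshold=0.9)
        assert at.n_censored == 5 and len(at.times) == 0
        assert np.isnan(at.mean)

    def test_threshold_validation(self, net):
        ens = run_ensemble(net, (0, 0, 0), 1.0, 2, base_seed=1,
                           algorithm="direct", record_trajectories=True)
        with pytest.raises(ValueError):
            adaptation_times(ens, 100, threshold=1.5)
        with pytest.raises(ValueError):
            adaptation_times(ens, -3)
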