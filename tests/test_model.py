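import dataclasses

import numpy as np
import pandas as pd
import pytest

import phipbayes as pb
from phipbayes.model import (
    BeerConfig,
    ChainState,
    _Sampler,
    _run_chain,
    call_enriched,
    initialize_chain,
    prefilter_super_enriched,
    run_mcmc,
)
from phipbayes.phipdata import PeptideCountMatrix
from phipbayes.priors import BeadsPrior, beta_shapes_from_moments


def simple_prior(mu0, tau=0.01):
    mu0 = np.asarray(mu0, float)
    a, b = beta_shapes_from_moments(mu0, tau * mu0**2)
    return BeadsPrior.from_shapes(
        [f"p{i}" for i in range(mu0.size)], a, b, "true"
    )


def matrix_for(Y, beads_rows=None):
    """One serum column plus two beads columns; row sums define libs."""
    Y = np.asarray(Y, int)
    if beads_rows is None:
        beads_rows = Y
    counts = pd.DataFrame(
        {"b1": beads_rows, "b2": beads_rows, "s": Y},
        index=[f"p{i}" for i in range(Y.size)],
    )
    roles = pd.Series({"b1": "beads", "b2": "beads", "s": "serum"})
    return PeptideCountMatrix(counts, roles)


class TestConfig:
    def test_defaults_match_applied_choices(self):
        cfg = BeerConfig()
        assert (cfg.a_pi, cfg.b_pi) == (2.0, 300.0)
        assert (cfg.a_phi, cfg.b_phi) == (1.25, 0.1)
        assert (cfg.a_c, cfg.b_c) == (80.0, 20.0)
        assert cfg.phi_min == 1.0 and cfg.prefilter_threshold == 15.0

    @pytest.mark.parametrize(
        "bad",
        [
            {"a_pi": 0.0},
            {"phi_min": 0.5},
            {"prefilter_threshold": 1.0},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            BeerConfig(**bad)


class TestInitialization:
    def test_twice_expected_count_rule_boundary(self):
        # 100 peptides at their expected count, one at exactly twice it
        Y = np.full(101, 100)
        Y[0] = 200
        m = matrix_for(Y)
        n = float(m.library_sizes["s"])
        prior = simple_prior(np.full(101, 100.0 / n))
        state = initialize_chain(m, prior, "s")
        assert bool(state.Z[0])  # 200 >= 2 * expected(100), boundary case
        assert not state.Z[1:].any()
        # one count fewer falls below the threshold
        Y2 = Y.copy()
        Y2[0] = 199
        m2 = matrix_for(Y2)
        prior2 = simple_prior(np.full(101, 100.0 / m2.library_sizes["s"]))
        state2 = initialize_chain(m2, prior2, "s")
        assert not state2.Z[0]

    def test_identity_data_offsets_c_and_pi(self):
        """All counts at expectation: slope 1, so c is offset inside (0,1);
        no enriched starts, so pi is offset to 1/P."""
        P, lib = 50, 10**6
        Y = np.full(P, lib // P)
        mu0 = np.full(P, 1.0 / P)
        prior = simple_prior(mu0)
        state = initialize_chain(matrix_for(Y), prior, "s")
        assert 0 < state.c < 1
        assert state.c == pytest.approx(1.0, abs=1e-3)
        assert state.pi == pytest.approx(1.0 / P)
        assert (state.phi == 1.0).all()

    def test_phi_init_formula(self):
        """Enriched start: phi = Y / (n c mu0) ~ 4 for a 4x count."""
        P = 101
        Y = np.full(P, 1000)
        Y[0] = 4000
        mu0 = np.full(P, np.nan)
        prior = None  # fill below with the realized library size
        m = matrix_for(Y)
        n = float(m.library_sizes["s"])
        mu0 = np.full(P, 1000.0 / n)
        prior = simple_prior(mu0)
        state = initialize_chain(m, prior, "s")
        assert bool(state.Z[0])
        assert state.phi[0] == pytest.approx(4.0, rel=2e-3)

    def test_beads_sample_as_serum_warns_but_runs(self, toy_matrix):
        prior = pb.estimate_mom(toy_matrix)
        with pytest.warns(UserWarning):
            initialize_chain(toy_matrix, prior, "b1")


class TestPrefilter:
    def _setup(self):
        P = 60
        Y = np.full(P, 1000)
        Y[0] = 40_000  # enormous enrichment
        beads = np.full(P, 1000)
        m = matrix_for(Y, beads_rows=beads)
        n = float(m.library_sizes["s"])
        mu0 = np.full(P, 1000.0 / n)
        return m, simple_prior(mu0)

    def test_super_enriched_removed_and_sizes_recomputed(self):
        m, prior = self._setup()
        filtered, excluded = prefilter_super_enriched(m, prior, "s", 15.0)
        assert list(excluded.index) == ["p0"]
        assert excluded.iloc[0] > 15
        removed = m.counts.loc["p0"]
        for s in m.sample_ids:
            assert (
                filtered.library_sizes[s] + removed[s]
                == m.library_sizes[s]
            )

    def test_no_super_enriched_is_identity(self):
        m, prior = self._setup()
        filtered, excluded = prefilter_super_enriched(m, prior, "s", 1e6)
        assert len(excluded) == 0
        assert filtered is m


class TestSamplerStationarity:
    def test_theta_update_is_conjugate_beta(self):
        """With (Z, phi, c) held fixed the theta draws must follow
        Beta(a + Y, b + n - Y)."""
        cfg = BeerConfig(seed=2)
        rng = np.random.default_rng(cfg.seed)
        mu0 = np.array([1e-3])
        s20 = 0.02 * mu0**2
        Y, n = np.array([1200.0]), 1e6
        smp = _Sampler(Y, n, mu0, s20, cfg, rng)
        state = ChainState(
            theta=mu0.copy(), Z=np.zeros(1, bool), phi=np.ones(1),
            c=0.9, pi=0.01,
        )
        draws = []
        for _ in range(4000):
            smp.update_theta(state)
            draws.append(state.theta[0])
        draws = np.array(draws)
        a, b = beta_shapes_from_moments(0.9 * mu0, s20)
        a_post, b_post = a[0] + Y[0], b[0] + n - Y[0]
        mean = a_post / (a_post + b_post)
        sd = np.sqrt(
            a_post * b_post
            / ((a_post + b_post) ** 2 * (a_post + b_post + 1))
        )
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.std() == pytest.approx(sd, rel=0.1)

    def test_prior_predictive_recovers_hyperpriors(self):
        """With no data (n = 0) the chain must sample the priors:
        E[c] = 80/100, E[pi] = 2/302, E[phi | Z=1] = 1 + 12.5."""
        P = 80
        mu0 = np.full(P, 1e-4)
        s20 = (0.1 * mu0) ** 2
        cfg = BeerConfig(n_iter=6000, n_burn=1000, seed=5)
        rng = np.random.default_rng(cfg.seed)
        smp = _Sampler(np.zeros(P), 0.0, mu0, s20, cfg, rng)
        state = ChainState(
            theta=mu0.copy(), Z=np.zeros(P, bool), phi=np.ones(P),
            c=0.8, pi=0.01,
        )
        pp, phi_hat, c_hat, pi_hat = _run_chain(
            smp, state, cfg, smp.log_marginal(state.phi, state.c)
        )
        assert c_hat == pytest.approx(0.8, abs=0.01)
        assert pi_hat == pytest.approx(2 / 302, abs=0.002)
        assert pp.mean() == pytest.approx(2 / 302, abs=0.003)
        slab_means = phi_hat[phi_hat > 1]
        assert slab_means.mean() == pytest.approx(13.5, rel=0.1)


class TestRunMcmc:
    def _spiked_instance(self, phi_true=32.0, tau=0.02, seed=0):
        rng = np.random.default_rng(seed)
        P = 120
        mu0 = np.full(P, 1e-4)
        s20 = tau * mu0**2
        n = 10**6
        mean = mu0.copy()
        mean[0] *= phi_true
        a, b = beta_shapes_from_moments(mean, s20)
        Y = rng.binomial(n, rng.beta(a, b))
        beads = rng.binomial(n, rng.beta(*beta_shapes_from_moments(mu0, s20)))
        m = matrix_for(Y, beads_rows=beads)
        n_act = float(m.library_sizes["s"])
        prior = simple_prior(np.full(P, 1e-4) * (n / n_act), tau)
        return m, prior

    def test_strong_spike_detected_with_certainty(self):
        """A 32-fold spike is either pre-filtered (prob 1) or sampled
        with posterior probability ~1."""
        m, prior = self._spiked_instance()
        cfg = BeerConfig(n_iter=1500, n_burn=400, seed=3)
        # without pre-filter
        big = dataclasses.replace(cfg, prefilter_threshold=1e6)
        summ = run_mcmc(m, prior, big, "s")
        assert summ.table.loc["p0", "post_prob"] >= 0.999
        # with the default pre-filter via the full pipeline
        summ2 = pb.run_beer(m, "s", config=cfg, prior=prior)
        assert summ2.table.loc["p0", "excluded"]
        assert summ2.table.loc["p0", "post_prob"] == 1.0

    def test_determinism(self):
        m, prior = self._spiked_instance(phi_true=4.0)
        cfg = BeerConfig(n_iter=400, n_burn=100, seed=11)
        s1 = run_mcmc(m, prior, cfg, "s")
        s2 = run_mcmc(m, prior, cfg, "s")
        pd.testing.assert_frame_equal(s1.table, s2.table)
        assert s1.c_hat == s2.c_hat and s1.pi_hat == s2.pi_hat


class TestCalls:
    def test_cutoff_behaviour(self):
        tab = pd.DataFrame(
            {
                "post_prob": [0.2, 0.6, 1.0],
                "phi_hat": [1.0, 2.0, 20.0],
                "excluded": [False, False, True],
            },
            index=["lo", "mid", "ex"],
        )
        s = pb.PosteriorSummary(tab, "s", 0.9, 0.01, 10, 1, 0)
        assert list(call_enriched(s, 0.5)) == [False, True, True]
        # near-1 cutoff keeps only certain/excluded peptides
        assert list(call_enriched(s, 0.999999)) == [False, False, True]
        # monotone non-increasing in the cutoff
        counts = [
            call_enriched(s, c).sum() for c in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


def test_fold_change_recovery_and_null_column(beer_run):
    """Posterior fold changes track truth for moderate spikes."""
    m, truth, summaries = beer_run
    errs = []
    for s, summ in summaries.items():
        z = truth.Z_true[s]
        phi = truth.phi_true[s]
        sel = (
            z & (phi >= 2) & (phi <= 8) & ~summ.table["excluded"]
        )
        est = summ.table.loc[sel, "phi_hat"]
        errs.extend(np.abs(est - phi[sel]) / phi[sel])
    assert np.mean(errs) <= 0.25
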