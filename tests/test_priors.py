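import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phipbayes.phipdata import PeptideCountMatrix
from phipbayes.nb import DispersionEstimate
from phipbayes.priors import (
    InfeasibleMomentsError,
    apply_guard,
    beta_moments,
    beta_shapes_from_moments,
    estimate_dispersion_derived,
    estimate_mle,
    estimate_mom,
    _beta_negloglik,
)


def beads_matrix(props, libs):
    """Single-peptide beads plate with exact proportions (2 peptides so
    columns sum to the library size)."""
    counts = {}
    for j, (p, n) in enumerate(zip(props, libs)):
        y = int(round(p * n))
        counts[f"b{j}"] = [y, n - y]
    df = pd.DataFrame(counts, index=["target", "rest"])
    roles = pd.Series("beads", index=df.columns)
    return PeptideCountMatrix(df, roles)


class TestMomentConversions:
    @pytest.mark.parametrize(
        "mu, sigma2, expected",
        [
            ((0.5), 0.05, (2.0, 2.0)),
            (0.2, 0.01, (3.0, 12.0)),
        ],
    )
    def test_shapes_from_moments(self, mu, sigma2, expected):
        a, b = beta_shapes_from_moments(mu, sigma2)
        assert a == pytest.approx(expected[0], rel=1e-12)
        assert b == pytest.approx(expected[1], rel=1e-12)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_shapes_from_moments(0.5, 0.25)

    @pytest.mark.parametrize(
        "a, b, expected",
        [(2.0, 2.0, (0.5, 0.05)), (1.0, 1.0, (0.5, 1 / 12))],
    )
    def test_beta_moments(self, a, b, expected):
        mu, s2 = beta_moments(a, b)
        assert (mu, s2) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(1e-2, 1e4),
        b=st.floats(1e-2, 1e4),
    )
    def test_round_trip_identity(self, a, b):
        """shapes -> moments -> shapes is the identity on feasible pairs."""
        mu, s2 = beta_moments(a, b)
        a2, b2 = beta_shapes_from_moments(mu, s2)
        assert a2 == pytest.approx(a, rel=1e-10)
        assert b2 == pytest.approx(b, rel=1e-10)


class TestGuard:
    def test_small_a_raised_preserving_mean(self):
        a, b = apply_guard(0.4, 399.6)
        assert (a, b) == (1.0, 999.0)
        assert a / (a + b) == pytest.approx(0.4 / 400.0)

    def test_identity_when_a_at_least_one(self):
        assert apply_guard(2.0, 5.0) == (2.0, 5.0)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(1e-4, 50.0), b=st.floats(1e-4, 1e6))
    def test_mean_always_preserved_and_a_at_least_one(self, a, b):
        a2, b2 = apply_guard(a, b)
        assert a2 >= 1.0
        assert a2 / (a2 + b2) == pytest.approx(a / (a + b), rel=1e-9)


class TestMom:
    def test_worked_example(self):
        """Beads proportions (0.1, 0.2, 0.3) give Beta(3, 12)."""
        m = beads_matrix([0.1, 0.2, 0.3], [1000, 1000, 1000])
        prior = estimate_mom(m)
        row = prior.table.loc["target"]
        assert row["mu0"] == pytest.approx(0.2)
        assert row["sigma2_0"] == pytest.approx(0.01)
        assert row["a0"] == pytest.approx(3.0, rel=1e-9)
        assert row["b0"] == pytest.approx(12.0, rel=1e-9)

    def test_constant_proportions_get_binomial_scale_variance(self):
        m = beads_matrix([0.2, 0.2, 0.2], [1000, 1000, 1000])
        prior = estimate_mom(m)
        row = prior.table.loc["target"]
        assert row["mu0"] == pytest.approx(0.2)
        # fallback: mu(1-mu)/(mean library size + 1)
        assert row["sigma2_0"] == pytest.approx(0.2 * 0.8 / 1001)

    def test_all_zero_peptide_gets_half_pseudo_read(self):
        counts = pd.DataFrame(
            {"b0": [0, 1000], "b1": [0, 2000]}, index=["zero", "rest"]
        )
        roles = pd.Series("beads", index=counts.columns)
        prior = estimate_mom(PeptideCountMatrix(counts, roles))
        assert prior.table.loc["zero", "mu0"] == pytest.approx(1 / 3000)

    def test_requires_two_beads_samples(self):
        counts = pd.DataFrame({"b0": [1, 9], "s": [2, 8]}, index=["x", "y"])
        roles = pd.Series({"b0": "beads", "s": "serum"})
        with pytest.raises(ValueError):
            estimate_mom(PeptideCountMatrix(counts, roles))


class TestMle:
    def test_recovers_true_shapes_at_large_n(self):
        rng = np.random.default_rng(0)
        n_samples, lib = 1000, 10**6
        theta = rng.beta(3.0, 12.0, n_samples)
        counts = {}
        for j in range(n_samples):
            y = int(round(theta[j] * lib))
            counts[f"b{j}"] = [y, lib - y]
        m = PeptideCountMatrix(
            pd.DataFrame(counts, index=["target", "rest"]),
            pd.Series("beads", index=list(counts)),
        )
        prior = estimate_mle(m)
        assert prior.table.loc["target", "a0"] == pytest.approx(3.0, rel=0.1)
        assert prior.table.loc["target", "b0"] == pytest.approx(12.0, rel=0.1)

    def test_optimum_at_least_as_likely_as_mom(self):
        rng = np.random.default_rng(1)
        x = rng.beta(2.0, 30.0, 50)
        mu, s2 = x.mean(), x.var(ddof=1)
        mom = np.array(beta_shapes_from_moments(mu, s2))
        counts = {
            f"b{j}": [int(round(v * 10**6)), 10**6 - int(round(v * 10**6))]
            for j, v in enumerate(x)
        }
        m = PeptideCountMatrix(
            pd.DataFrame(counts, index=["target", "rest"]),
            pd.Series("beads", index=list(counts)),
        )
        mle = estimate_mle(m)
        fitted = mle.table.loc["target", ["a0", "b0"]].to_numpy(float)
        assert _beta_negloglik(fitted, x) <= _beta_negloglik(mom, x) + 1e-6

    def test_degenerate_data_falls_back_to_mom(self):
        m = beads_matrix([0.2, 0.2, 0.2], [1000, 1000, 1000])
        mle = estimate_mle(m)
        mom = estimate_mom(m)
        pd.testing.assert_frame_equal(mle.table, mom.table)


class TestDispersionDerived:
    def _matrix_with_theta0(self, theta0):
        lib = 10**6
        y = int(round(theta0 * lib))
        counts = pd.DataFrame(
            {"b0": [y, lib - y], "b1": [y, lib - y]},
            index=["target", "rest"],
        )
        return PeptideCountMatrix(
            counts, pd.Series("beads", index=counts.columns)
        )

    def test_formula(self):
        """sigma2 = tau * theta0^2: theta0=1e-3, tau=0.04 -> a ~ 24.974."""
        m = self._matrix_with_theta0(1e-3)
        disp = DispersionEstimate(
            0.04, np.array([0.04, 0.04]), 10.0, m.peptide_ids
        )
        prior = estimate_dispersion_derived(m, disp)
        row = prior.table.loc["target"]
        assert row["sigma2_0"] == pytest.approx(4e-8)
        assert row["a0"] == pytest.approx(24.974, abs=1e-3)
        assert row["b0"] == pytest.approx(row["a0"] * 999, rel=1e-9)

    def test_a_decreasing_in_tau(self):
        m = self._matrix_with_theta0(1e-3)
        a_vals = []
        for tau in [0.01, 0.02, 0.05, 0.1, 0.3]:
            disp = DispersionEstimate(
                tau, np.array([tau, tau]), 10.0, m.peptide_ids
            )
            a_vals.append(
                estimate_dispersion_derived(m, disp).table.loc["target", "a0"]
            )
        assert all(x > y for x, y in zip(a_vals, a_vals[1:]))

    def test_zero_tau_uses_degenerate_fallback(self):
        m = self._matrix_with_theta0(1e-3)
        disp = DispersionEstimate(
            0.0, np.zeros(2), 10.0, m.peptide_ids
        )
        prior = estimate_dispersion_derived(m, disp)
        mu = prior.table.loc["target", "mu0"]
        assert prior.table.loc["target", "sigma2_0"] == pytest.approx(
            mu * (1 - mu) / (10**6 + 1)
        )

    def test_missing_peptide_in_dispersion_rejected(self):
        m = self._matrix_with_theta0(1e-3)
        disp = DispersionEstimate(
            0.04, np.array([0.04]), 10.0, pd.Index(["target"])
        )
        with pytest.raises(KeyError):
            estimate_dispersion_derived(m, disp)


def test_estimators_recover_background_mean(estimated_plate):
    """All routes agree on mu0 for beads columns of a simulated plate."""
    import phipbayes as pb

    m, _, gen_prior = estimated_plate
    theta = m.beads_counts().to_numpy(float) / m.library_sizes[
        m.beads_ids
    ].to_numpy(float)
    emp = theta.mean(axis=1)
    for est in (pb.estimate_mom(m), pb.estimate_prior(m, "edger")):
        np.testing.assert_allclose(est.mu0, emp, rtol=1e-8)
        assert (est.a0 >= 1.0).all()
        assert (est.b0 > 0).all()
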