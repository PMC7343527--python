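"""Variational Laplace: features, free energy, oracles, multistart."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gendcm.inversion import (
    feature_vector,
    features_to_csd,
    free_energy,
    make_csd_predictor,
    multistart_invert,
    variational_laplace,
)
from gendcm.params import ParameterSet, condition_parameters, default_b_indices
from gendcm.spectral import CSDDataset, predict_csd

GRID = np.linspace(5.0, 45.0, 11)


def _random_hermitian_csd(rng, nf=7, nc=2, conditions=("OFF", "ON")):
    freq = np.linspace(5, 45, nf)
    G = {}
    for cond in conditions:
        X = rng.normal(size=(nf, nc, 3)) + 1j * rng.normal(size=(nf, nc, 3))
        G[cond] = X @ np.conj(np.swapaxes(X, 1, 2))
    return CSDDataset(freq=freq, G=G, channels=tuple(f"c{i}" for i in range(nc)))


class TestFeatureVector:
    def test_length_counts_diag_and_upper_triangle(self):
        rng = np.random.default_rng(0)
        csd = _random_hermitian_csd(rng, nf=41, nc=2)
        v = feature_vector(csd)
        # per frequency and condition: 2 real autos + Re & Im of the pair
        assert v.size == 2 * 41 * (2 + 2)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_reconstruction_exact(self, seed):
        rng = np.random.default_rng(seed)
        csd = _random_hermitian_csd(rng, nf=5, nc=3)
        v = feature_vector(csd)
        back = features_to_csd(v, csd.freq, csd.channels, csd.conditions)
        for cond in csd.conditions:
            np.testing.assert_allclose(back.G[cond], csd.G[cond], atol=1e-12)

    def test_zero_matrix_maps_to_zero_vector(self):
        csd = CSDDataset(
            freq=GRID, G={"x": np.zeros((11, 2, 2), complex)}, channels=("a", "b")
        )
        assert np.all(feature_vector(csd) == 0.0)

    def test_non_hermitian_rejected(self):
        G = np.zeros((11, 2, 2), complex)
        G[:, 0, 1] = 1.0  # missing conjugate partner
        csd = CSDDataset(freq=GRID, G={"x": G}, channels=("a", "b"))
        with pytest.raises(ValueError, match="Hermitian"):
            feature_vector(csd)


class TestFreeEnergy:
    def test_zero_residual_at_prior_centre(self):
        n = 10
        r = np.zeros(n)
        Pi = np.eye(4)
        F = free_energy(r, np.zeros(4), 16.0, Pi, 16.0, 4.0)
        assert F == pytest.approx(0.5 * n * (16.0 - np.log(2 * np.pi)))

    def test_doubling_residual_quadruples_accuracy_penalty(self):
        Pi = np.eye(3)
        r1 = np.full(5, 0.1)
        base = free_energy(np.zeros(5), np.zeros(3), 2.0, Pi, 16.0, 4.0)
        p1 = base - free_energy(r1, np.zeros(3), 2.0, Pi, 16.0, 4.0)
        p2 = base - free_energy(2 * r1, np.zeros(3), 2.0, Pi, 16.0, 4.0)
        assert p2 == pytest.approx(4 * p1, rel=1e-12)

    def test_decreases_with_residual_growth(self):
        Pi = np.eye(2)
        Fs = [
            free_energy(np.full(4, s), np.zeros(2), 1.0, Pi, 16.0, 4.0)
            for s in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(Fs, Fs[1:]))


class TestLinearGaussianOracle:
    """On g(theta) = X theta the posterior is conjugate and exactly known."""

    def _setup(self, seed=3, n=40, p=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        theta_true = rng.normal(0, 0.5, p)
        y = X @ theta_true + rng.normal(0, 0.03, n)
        Pi = np.diag(np.full(p, 4.0))
        return X, y, Pi

    def test_posterior_matches_conjugate_closed_form(self):
        X, y, Pi = self._setup()
        res = variational_laplace(lambda th: X @ th, y, np.zeros(5), Pi)
        lam = res.lam
        H = np.exp(lam) * X.T @ X + Pi
        mean = np.linalg.solve(H, np.exp(lam) * X.T @ y)
        cov = np.linalg.inv(H)
        np.testing.assert_allclose(res.posterior_mean, mean, atol=1e-6)
        np.testing.assert_allclose(res.posterior_cov, cov, atol=1e-6)

    def test_free_energy_maximised_at_analytic_mean(self):
        X, y, Pi = self._setup(seed=4)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(5), Pi)
        lam, m = res.lam, res.posterior_mean

        def F_at(th):
            return free_energy(y - X @ th, th, lam, Pi, 16.0, 4.0)

        F_star = F_at(m)
        rng = np.random.default_rng(5)
        for _ in range(20):
            assert F_at(m + rng.normal(0, 0.01, 5)) < F_star

    def test_trace_nondecreasing(self):
        X, y, Pi = self._setup(seed=6)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(5), Pi)
        assert np.all(np.diff(res.F_trace) >= -1e-9)

    def test_posterior_covariance_psd(self):
        X, y, Pi = self._setup(seed=7)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(5), Pi)
        w = np.linalg.eigvalsh(res.posterior_cov)
        assert np.all(w > 0)


class TestPriorOnlyFit:
    def test_empty_data_returns_prior(self):
        Pi = np.diag([2.0, 5.0])
        res = variational_laplace(
            lambda th: np.zeros(0), np.zeros(0), np.array([0.3, -0.2]), Pi
        )
        np.testing.assert_allclose(res.posterior_mean, [0.3, -0.2], atol=1e-12)
        np.testing.assert_allclose(res.posterior_cov, np.linalg.inv(Pi), atol=1e-10)


class TestConditionEffects:
    def test_zero_B_gives_identical_conditions(self, network, priors, theta0):
        off = condition_parameters(theta0, priors, network, "baseline")
        on = condition_parameters(theta0, priors, network, "modulated")
        np.testing.assert_array_equal(off["gamma"]["bgt"], on["gamma"]["bgt"])
        np.testing.assert_array_equal(off["A"], on["A"])

    def test_log_halving_effect(self, network, priors):
        ps = ParameterSet(priors.layout)
        ps["B_bgt"][3] = np.log(0.5)  # GPe -> STN
        off = condition_parameters(ps, priors, network, "baseline")
        on = condition_parameters(ps, priors, network, "modulated")
        assert on["gamma"]["bgt"][3] == pytest.approx(0.5 * off["gamma"]["bgt"][3])
        others = [i for i in range(9) if i != 3]
        np.testing.assert_array_equal(
            on["gamma"]["bgt"][others], off["gamma"]["bgt"][others]
        )

    def test_ext_group_shared_between_thalamocortical_arrows(self, network, priors):
        ps = ParameterSet(priors.layout)
        ps["B_ext"][0] = np.log(2.0)
        on = condition_parameters(ps, priors, network, "modulated")
        off = condition_parameters(ps, priors, network, "baseline")
        np.testing.assert_allclose(on["A"][:2], 2.0 * off["A"][:2])
        np.testing.assert_array_equal(on["A"][2:], off["A"][2:])

    def test_undeclared_b_index_rejected(self, network, priors):
        ps = ParameterSet(priors.layout)
        ps["B_mmc"][5] = 0.2
        b = default_b_indices(network)
        b["mmc"] = (1, 2, 3)  # connection 6 not declared
        with pytest.raises(ValueError, match="b_indices"):
            condition_parameters(ps, priors, network, "modulated", b)

    def test_unknown_condition_rejected(self, network, priors, theta0):
        with pytest.raises(ValueError):
            condition_parameters(theta0, priors, network, "sideways")


class TestSelfConsistency:
    def test_noise_free_data_recovers_prior_centre(self, network, priors):
        """Data generated at the prior means are explained there exactly."""
        b_idx = default_b_indices(network)
        predict = make_csd_predictor(network, priors, GRID, ("OFF", "ON"), b_idx)
        y = predict(np.zeros(priors.layout.n_params))
        res = variational_laplace(
            predict, y, np.zeros(priors.layout.n_params), priors.precision(),
            maxiter=8,
        )
        for name, _ in priors.layout.blocks:
            sl = priors.layout.slices()[name]
            assert np.max(np.abs(res.posterior_mean[sl])) < 0.05, name
        assert res.F_trace[-1] > res.F_trace[0]
        assert np.all(np.diff(res.F_trace) >= -1e-9)

    def test_true_parameters_are_retained_from_a_warm_start(self, network, priors):
        """Noiseless spectra keep a warm-started fit at the generating
        parameters, and that optimum dominates the cold-started one."""
        truth = ParameterSet(priors.layout)
        truth["gamma_bgt"][4] = 0.3  # STN -> GPe strengthened
        truth["L"] = 4.0
        truth["alpha_c"] = -2.0
        truth["alpha_s"] = -2.0
        predict = make_csd_predictor(network, priors, GRID, ("OFF",))
        y = predict(truth.theta)
        warm = variational_laplace(
            predict, y, np.zeros(priors.layout.n_params), priors.precision(),
            x0=truth.theta, maxiter=16,
        )
        est = ParameterSet(priors.layout, warm.posterior_mean)
        assert est["gamma_bgt"][4] == pytest.approx(0.3, abs=0.05)
        cold = variational_laplace(
            predict, y, np.zeros(priors.layout.n_params), priors.precision(),
            maxiter=16,
        )
        assert warm.F > cold.F


class TestMultistart:
    def _toy(self, seed=8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 4))
        y = X @ rng.normal(0, 0.5, 4) + rng.normal(0, 0.05, 30)
        return X, y, np.eye(4) * 4.0

    def test_single_restart_identical_to_plain_run(self):
        X, y, Pi = self._toy()
        a = variational_laplace(lambda th: X @ th, y, np.zeros(4), Pi)
        b = multistart_invert(lambda th: X @ th, y, np.zeros(4), Pi, n_restarts=1)
        assert a.F == pytest.approx(b.F, abs=1e-12)
        np.testing.assert_allclose(a.posterior_mean, b.posterior_mean, atol=1e-12)

    def test_returned_F_dominates_every_restart(self):
        X, y, Pi = self._toy(seed=9)
        res = multistart_invert(lambda th: X @ th, y, np.zeros(4), Pi, n_restarts=3)
        assert res.F >= max(res.restart_F) - 1e-12
        assert len(res.restart_F) == 3

    def test_restarting_from_distant_init_recovers(self, network, priors):
        predict = make_csd_predictor(network, priors, GRID[::2], ("OFF",))
        y = predict(np.zeros(priors.layout.n_params))
        far = np.zeros(priors.layout.n_params)
        far[:14] = 0.4  # displace the cortical couplings
        single = variational_laplace(
            predict, y, np.zeros(priors.layout.n_params), priors.precision(),
            x0=far, maxiter=8,
        )
        chained = multistart_invert(
            predict, y, np.zeros(priors.layout.n_params), priors.precision(),
            n_restarts=2, x0=far, maxiter=8,
        )
        assert chained.F >= single.F - 1e-9

    def test_invalid_restart_count(self):
        X, y, Pi = self._toy()
        with pytest.raises(ValueError):
            multistart_invert(lambda th: X @ th, y, np.zeros(4), Pi, n_restarts=0)


class TestModelFacade:
    def test_fit_on_tiny_noise_free_dataset(self, network, priors):
        from gendcm.model import SpectralDCM

        ps = ParameterSet(priors.layout)
        nat_off = condition_parameters(ps, priors, network, "baseline")
        nat_on = condition_parameters(ps, priors, network, "modulated")
        freq = GRID[::2]
        data = CSDDataset(
            freq=freq,
            G={
                "OFF": predict_csd(network, nat_off, freq).G["prediction"],
                "ON": predict_csd(network, nat_on, freq).G["prediction"],
            },
            channels=("M1", "STN"),
        )
        model = SpectralDCM(data)
        res = model.fit(maxiter=4)
        assert res.F_trace[-1] >= res.F_trace[0]
        assert np.max(np.abs(res.params.theta)) < 0.05
        s = res.summary()
        assert "free energy" in s and "gamma_mmc" in s
        frame = res.summary_frame()
        assert len(frame) == priors.layout.n_params
        pred = res.predicted
        assert set(pred) == {"OFF", "ON"}
        pop = res.population_spectrum("mmc", "DP")
        assert pop.shape == freq.shape and np.all(pop >= 0)
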