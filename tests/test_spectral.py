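"""Spectral forward model: linearization, delays, CSD prediction, coherence."""

import numpy as np
import pytest

from conftest import single_pop_params
from gendcm.network import build_delay_matrix
from gendcm.params import ParameterSet, build_priors, condition_parameters
from gendcm.spectral import (
    UnstableModelError,
    coherence,
    delay_embed,
    jacobian,
    linearize,
    population_spectra,
    predict_csd,
    transfer_function,
)

FREQ = np.linspace(5.0, 45.0, 41)


class TestLinearize:
    def test_matches_closed_form_jacobian(self, network, nat_params):
        sm = linearize(network, nat_params)
        Ja = jacobian(network, nat_params)
        scale = np.max(np.abs(Ja))
        assert np.max(np.abs(sm.J - Ja)) < 1e-8 * scale

    def test_input_columns_only_on_input_populations(self, network, nat_params):
        sm = linearize(network, nat_params)
        nz = np.nonzero(sm.U)
        expected_rows = {
            network.vdot_index("mmc", "MP"),
            network.vdot_index("bgt", "Str"),
        }
        assert set(nz[0]) == expected_rows
        assert sm.U.shape == (18, 2)

    def test_stable_at_prior_means(self, network, nat_params):
        sm = linearize(network, nat_params)
        assert np.max(np.linalg.eigvals(sm.J).real) < 0

    def test_rejects_non_fixed_point(self, network, nat_params):
        with pytest.raises(ValueError, match="fixed point"):
            linearize(network, nat_params, operating_point=np.full(18, 0.3))

    def test_single_population_closed_form(self, single_pop_network):
        T = 0.01
        sm = linearize(single_pop_network, single_pop_params(T_s=T))
        np.testing.assert_allclose(
            sm.J, [[0.0, 1.0], [-1.0 / T**2, -2.0 / T]], rtol=1e-6
        )


class TestDelayEmbed:
    def test_zero_delay_identity(self, network, nat_params):
        J = jacobian(network, nat_params)
        D = build_delay_matrix(network, np.zeros(4))
        np.testing.assert_array_equal(delay_embed(J, D), J)

    def test_scalar_case(self):
        # x' = -a x(t - d)  ->  first-order embedding -a / (1 - d a)
        a, d = 3.0, 0.05
        Jd = delay_embed(np.array([[-a]]), np.array([[d]]))
        assert Jd[0, 0] == pytest.approx(-a / (1.0 - d * a), rel=1e-12)

    def test_eigenvalue_shift_first_order_in_delay(self, network, nat_params):
        J = jacobian(network, nat_params)
        ev0 = np.sort(np.linalg.eigvals(J).real)
        shifts = []
        for scale in (1.0, 0.5):
            D = build_delay_matrix(network, scale * np.array([1, 8, 8, 4.0]) * 1e-4)
            ev = np.sort(np.linalg.eigvals(delay_embed(J, D)).real)
            shifts.append(np.max(np.abs(ev - ev0)))
        assert shifts[1] == pytest.approx(shifts[0] / 2, rel=0.2)


class TestPredictCSD:
    def test_zero_lead_field_leaves_noise_floor(self, single_pop_network):
        p = single_pop_params(L=0.0, noise={"alpha_c": 0.3, "alpha_s": 0.7})
        csd = predict_csd(single_pop_network, p, FREQ)
        floor = (0.3 + 0.7) * FREQ ** (-1.0)
        np.testing.assert_allclose(csd.G["prediction"][:, 0, 0].real, floor, rtol=1e-12)

    def test_single_population_closed_form(self, single_pop_network):
        T = 0.01
        p = single_pop_params(T_s=T)
        csd = predict_csd(single_pop_network, p, FREQ, input_gain=512.0)
        w = 2 * np.pi * FREQ
        expected = 512.0 * FREQ ** (-1.0) * T**2 / ((1 - w**2 * T**2) ** 2 + 4 * w**2 * T**2)
        got = csd.G["prediction"][:, 0, 0].real
        assert np.max(np.abs(got - expected) / expected) < 1e-8

    def test_transfer_magnitude_closed_form(self, single_pop_network):
        # |H| = T / |1 + i w T|^2 across the analysis band
        T = 0.01
        H = transfer_function(single_pop_network, single_pop_params(T_s=T), FREQ)
        w = 2 * np.pi * FREQ
        expected = T / np.abs(1 + 1j * w * T) ** 2
        assert np.max(np.abs(np.abs(H[:, 0, 0]) - expected) / expected) < 1e-8

    def test_hermitian_psd_at_priors(self, network, nat_params):
        G = predict_csd(network, nat_params, FREQ).G["prediction"]
        np.testing.assert_allclose(G, np.conj(np.swapaxes(G, 1, 2)), atol=1e-12)
        diag = np.einsum("fcc->fc", G)
        assert np.all(diag.real > 0) and np.max(np.abs(diag.imag)) < 1e-15

    def test_auto_exceeds_cross_magnitude(self, network, nat_params):
        G = predict_csd(network, nat_params, FREQ).G["prediction"]
        cross = np.abs(G[:, 0, 1]) ** 2
        assert np.all(cross <= G[:, 0, 0].real * G[:, 1, 1].real + 1e-18)

    def test_hermitian_psd_for_prior_draws(self, network, priors):
        """Stable prior draws always yield Hermitian PSD matrices with
        coherence in [0, 1] (seeded, 200 evaluated draws)."""
        rng = np.random.default_rng(7)
        sd = np.sqrt(priors.sigma2)
        checked = 0
        attempts = 0
        while checked < 200 and attempts < 4000:
            attempts += 1
            ps = ParameterSet(priors.layout, rng.normal(0, 1, priors.layout.n_params) * sd)
            nat = condition_parameters(ps, priors, network, "baseline")
            try:
                csd = predict_csd(network, nat, FREQ[::8])
            except (UnstableModelError, np.linalg.LinAlgError):
                continue
            G = csd.G["prediction"]
            assert np.allclose(G, np.conj(np.swapaxes(G, 1, 2)), atol=1e-10)
            diag = np.einsum("fcc->fc", G).real
            assert np.all(diag > 0)
            C = coherence(csd)["prediction"]
            assert np.all(C >= -1e-12) and np.all(C <= 1 + 1e-12)
            checked += 1
        assert checked >= 200, f"only {checked} stable draws in {attempts} attempts"

    def test_channel_noise_floor_monotone_in_alpha_s(self, network, nat_params):
        import copy

        p2 = copy.deepcopy(nat_params)
        p2["noise"]["alpha_s"] *= 2.0
        G1 = predict_csd(network, nat_params, FREQ).G["prediction"]
        G2 = predict_csd(network, p2, FREQ).G["prediction"]
        diag1 = np.einsum("fcc->fc", G1).real
        diag2 = np.einsum("fcc->fc", G2).real
        assert np.all(diag2 > diag1)
        off = np.abs(G2[:, 0, 1] - G1[:, 0, 1])
        assert np.max(off) < 1e-14

    def test_unstable_parameters_flagged(self, network, nat_params):
        import copy

        p2 = copy.deepcopy(nat_params)
        p2["gamma"]["bgt"] = nat_params["gamma"]["bgt"] * 8.0  # blow up the loop gain
        with pytest.raises(UnstableModelError):
            predict_csd(network, p2, FREQ)


class TestCoherence:
    def test_unity_on_diagonal(self, network, nat_params):
        C = coherence(predict_csd(network, nat_params, FREQ))["prediction"]
        np.testing.assert_allclose(C[:, 0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(C[:, 1, 1], 1.0, atol=1e-12)

    def test_independent_channels_zero(self):
        from gendcm.spectral import CSDDataset

        freq = FREQ[:5]
        G = np.tile(np.diag([2.0, 3.0]).astype(complex), (5, 1, 1))
        csd = CSDDataset(freq=freq, G={"x": G}, channels=("a", "b"))
        C = coherence(csd)["x"]
        np.testing.assert_allclose(C[:, 0, 1], 0.0, atol=1e-15)

    def test_rank_one_common_source_is_unity(self):
        from gendcm.spectral import CSDDataset

        freq = FREQ[:4]
        h = np.array([1.0 + 0.5j, 0.3 - 0.2j])
        G1 = np.outer(h, h.conj())
        G = np.tile(G1, (4, 1, 1))
        csd = CSDDataset(freq=freq, G={"x": G}, channels=("a", "b"))
        C = coherence(csd)["x"]
        np.testing.assert_allclose(C[:, 0, 1], 1.0, atol=1e-12)


class TestPopulationSpectra:
    def test_mixture_sum_rule(self, network, nat_params):
        """The M1 channel auto-spectrum is the quadratic form of the
        SP/MP/DP cross-spectral block with the output mixture (channel
        noise removed), by bilinearity of G in the observation row."""
        csd_sig = predict_csd(network, nat_params, FREQ, channel_noise=False)
        got = csd_sig.G["prediction"][:, 0, 0].real / nat_params["L"][0] ** 2

        mix = {"SP": 0.2, "MP": 0.2, "DP": 0.6}
        # cross-spectra between populations via unit virtual electrodes:
        # build from transfer rows directly
        from gendcm.spectral import _embedded_jacobian, input_matrix

        Jd = _embedded_jacobian(network, nat_params)
        U = input_matrix(network, nat_params)
        g_u = 512.0 * FREQ ** (-1.0)
        n = Jd.shape[0]
        rows = np.zeros((3, n))
        for i, pop in enumerate(mix):
            rows[i, network.v_index("mmc", pop)] = 1.0
        acc = np.zeros(FREQ.size)
        w = np.array(list(mix.values()))
        for k, f in enumerate(FREQ):
            h = rows @ np.linalg.solve(2j * np.pi * f * np.eye(n) - Jd, U)
            block = g_u[k] * (h @ h.conj().T)
            acc[k] = np.real(w @ block @ w)
        np.testing.assert_allclose(got, acc, rtol=1e-9)

    def test_every_population_addressable(self, network, nat_params):
        s = population_spectra(network, nat_params, FREQ[::10], "mmc", "II")
        assert s.shape == (len(FREQ[::10]),) and np.all(s >= 0)

    def test_unknown_population(self, network, nat_params):
        with pytest.raises(KeyError):
            population_spectra(network, nat_params, FREQ, "mmc", "GPe")

    def test_nonnegative_everywhere(self, network, nat_params):
        for src, pop in (("mmc", "DP"), ("bgt", "GPe"), ("bgt", "Tha")):
            s = population_spectra(network, nat_params, FREQ, src, pop)
            assert np.all(s >= 0) and np.all(np.isfinite(s))
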