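"""Next-generation-matrix structure, closed forms, and their equivalence.

The closed-form R0 expressions are checked against the independent
numeric route (spectral radius of -T Sigma^{-1}) on random ensembles,
against hand-evaluated values, and through the exact reduction chain
linking the latency models to the lytic baseline.
"""

import json

import numpy as np
import pytest

import virofit as vf
from virofit.ngm import spectral_gap
from virofit.sampling import sample_parameters


@pytest.fixture
def lytic_params():
    return vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                               d=0.0, d_prime=0.24, beta=50.0,
                               m=1.0 / 24.0, eta=10.0)


class TestDecompositionStructure:
    def test_lytic_matrices_match_printed_forms(self, lytic_params):
        S = 1e7
        d = vf.build_ngm("lytic", lytic_params, S)
        phiS = lytic_params.phi * S
        np.testing.assert_allclose(d.T, [[0.0, phiS], [0.0, 0.0]])
        np.testing.assert_allclose(
            d.Sigma,
            [[-10.0 - 0.24, 0.0], [50.0 * 10.0, -phiS - 1.0 / 24.0]],
        )
        assert d.compartment_labels == ("I", "V")

    def test_latent_explicit_fully_lysogenic_transmission_rows(self):
        params = vf.LatentExplicitParameters(
            b=1.0, b_prime=0.54, K=7.5e7, phi=6.7e-10, d=0.0, d_prime=0.44,
            beta=50.0, m=0.04, eta=1.0, q_l=1.0, gamma=0.0)
        S = 2e7
        d = vf.build_ngm("latent_explicit", params, S)
        phiS = params.phi * S
        headroom = 1.0 - S / params.K
        assert np.all(d.T[0] == 0.0)  # no inflow to the lytic class
        np.testing.assert_allclose(
            d.T[1], [0.0, 0.54 * headroom, phiS])

    def test_chronic_at_zero_density_is_purely_vertical(self):
        params = vf.fixture("fig4_chronic")
        d = vf.build_ngm("chronic", params, 0.0)
        np.testing.assert_allclose(d.T, [[0.68, 0.0], [0.0, 0.0]])

    @pytest.mark.parametrize("model_id", vf.MODEL_IDS)
    def test_sign_structure(self, model_id, rng):
        for _ in range(50):
            params = sample_parameters(model_id, rng)
            S = rng.uniform(0.0, params.K)
            d = vf.build_ngm(model_id, params, S)
            assert np.all(d.T >= 0.0)
            assert np.all(np.diag(d.Sigma) < 0.0)
            off = d.Sigma - np.diag(np.diag(d.Sigma))
            assert np.all(off >= 0.0)

    def test_gamma_nonzero_is_rejected(self):
        params = vf.LatentExplicitParameters(
            b=1.0, b_prime=0.54, K=7.5e7, phi=6.7e-10, d=0.0, d_prime=0.44,
            beta=50.0, m=0.04, eta=1.0, q_l=0.5, gamma=0.1)
        with pytest.raises(vf.UnsupportedConfigurationError):
            vf.build_ngm("latent_explicit", params, 1e7)
        with pytest.raises(vf.UnsupportedConfigurationError):
            vf.r0_latent_explicit_closed(params, 1e7)

    def test_non_finite_density_is_rejected(self, lytic_params):
        with pytest.raises(vf.NGMError):
            vf.build_ngm("lytic", lytic_params, np.nan)


class TestExpectedDurations:
    def test_lytic_durations_match_closed_inverse(self, lytic_params):
        S = 1e7
        d = vf.build_ngm("lytic", lytic_params, S)
        durations = vf.expected_durations(d)
        phiS = lytic_params.phi * S
        eta, dp, m, beta = 10.0, 0.24, 1.0 / 24.0, 50.0
        expected = [
            [1.0 / (eta + dp), 0.0],
            [beta / (phiS + m) * eta / (eta + dp), 1.0 / (phiS + m)],
        ]
        np.testing.assert_allclose(durations, expected, rtol=1e-14)

    def test_chronic_durations_without_adsorption(self):
        params = vf.ChronicParameters(b=1.0, b_prime=0.68, K=7.5e7, phi=0.0,
                                      d=0.0, d_prime=0.63, beta=1.0, m=0.04,
                                      eta=0.0, alpha=20.0)
        durations = vf.expected_durations(vf.build_ngm("chronic", params, 1e7))
        expected = [[1.0 / 0.63, 0.0],
                    [20.0 / (0.63 * 0.04), 1.0 / 0.04]]
        np.testing.assert_allclose(durations, expected, rtol=1e-14)

    @pytest.mark.parametrize("model_id", vf.MODEL_IDS)
    def test_durations_are_nonnegative(self, model_id, rng):
        for _ in range(100):
            params = sample_parameters(model_id, rng)
            S = rng.uniform(0.0, params.K)
            durations = vf.expected_durations(vf.build_ngm(model_id, params, S))
            assert np.all(durations >= 0.0)

    def test_non_dissipative_subsystem_raises(self):
        params = vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                                     d=0.0, d_prime=0.0, beta=50.0,
                                     m=0.04, eta=0.0)
        with pytest.raises(vf.DegenerateModelError):
            vf.expected_durations(vf.build_ngm("lytic", params, 1e7))


class TestClosedForms:
    def test_lytic_hand_value(self):
        params = vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                                     d=0.0, d_prime=0.0, beta=50.0,
                                     m=1.0 / 24.0, eta=1.0)
        report = vf.r0_lytic_closed(params, 1e7)
        expected = 50.0 * 6.7e-3 / (6.7e-3 + 1.0 / 24.0)
        assert report.total == pytest.approx(expected, rel=1e-14)
        assert report.total == pytest.approx(6.93, abs=0.005)
        assert report.vertical == 0.0

    def test_lytic_limits(self):
        params = vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                                     d=0.0, d_prime=0.0, beta=50.0,
                                     m=0.0, eta=1.0)
        assert vf.r0_lytic_closed(params, 1e7).total == pytest.approx(50.0)
        params = params.replace(m=0.04)
        assert vf.r0_lytic_closed(params, 0.0).total == 0.0

    def test_pure_lysogeny_hand_value(self):
        params = vf.LatentImplicitParameters(
            b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10, d=0.0, d_prime=0.24,
            beta=50.0, m=0.04, eta=1.0, p=0.0, q=1.0)
        report = vf.r0_latent_implicit_closed(params, 0.5 * params.K)
        assert report.horizontal == 0.0
        assert report.total == pytest.approx(0.5 / 0.24, rel=1e-14)
        assert report.total == pytest.approx(2.083, abs=2e-3)

    def test_chronic_hand_value(self):
        params = vf.fixture("fig4_chronic")
        report = vf.r0_chronic_closed(params, params.K / 2.0)
        phiS = 3.4e-10 * 3.75e7
        expected_hor = 20.0 / 0.63 * phiS / (phiS + 0.04)
        expected_ver = 0.68 * 0.5 / 0.63
        assert report.horizontal == pytest.approx(expected_hor, rel=1e-14)
        assert report.vertical == pytest.approx(expected_ver, rel=1e-14)
        assert report.total == pytest.approx(8.21, abs=0.005)
        # no logistic headroom at carrying capacity
        assert vf.r0_chronic_closed(params, params.K).vertical == 0.0

    def test_latent_explicit_is_max_of_branches(self):
        params = vf.LatentExplicitParameters(
            b=1.0, b_prime=0.54, K=7.5e7, phi=6.7e-10, d=0.0, d_prime=0.44,
            beta=50.0, m=0.04, eta=1.0, q_l=0.3, gamma=0.0)
        report = vf.r0_latent_explicit_closed(params, 1e7)
        assert report.total == max(report.horizontal, report.vertical)
        assert report.reducible
        fully_latent = vf.r0_latent_explicit_closed(params.replace(q_l=1.0), 1e7)
        assert fully_latent.total == fully_latent.vertical
        assert not fully_latent.reducible

    def test_report_serialization_keys(self, lytic_params):
        payload = json.loads(vf.r0_lytic_closed(lytic_params, 1e7).to_json())
        assert set(payload) == {"model", "method", "S_star", "R0_total",
                                "R0_horizontal", "R0_vertical"}

    def test_degenerate_denominators_raise(self):
        immortal = vf.LatentImplicitParameters(
            b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10, d=0.0, d_prime=0.0,
            beta=50.0, m=0.04, eta=1.0, p=0.0, q=1.0)
        with pytest.raises(vf.DegenerateModelError):
            vf.r0_latent_implicit_closed(immortal, 1e7)
        no_sink = vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                                      d=0.0, d_prime=0.24, beta=50.0,
                                      m=0.0, eta=1.0)
        with pytest.raises(vf.DegenerateModelError):
            vf.r0_lytic_closed(no_sink, 0.0)


class TestNumericRoute:
    def test_lytic_spectral_radius_equals_closed_form(self):
        params = vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                                     d=0.0, d_prime=0.0, beta=50.0,
                                     m=1.0 / 24.0, eta=10.0)
        closed = vf.r0_lytic_closed(params, 1e7).total
        numeric = vf.r0_numeric(vf.build_ngm("lytic", params, 1e7)).total
        assert numeric == pytest.approx(closed, rel=1e-10)

    def test_survival_fractions_of_one_give_burst_size(self):
        params = vf.CommonParameters(b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10,
                                     d=0.0, d_prime=0.0, beta=50.0,
                                     m=0.0, eta=1.0)
        report = vf.r0_numeric(vf.build_ngm("lytic", params, 1e7))
        assert report.total == pytest.approx(50.0, rel=1e-12)
        assert report.method == "ngm_numeric"
        assert report.horizontal is None and report.vertical is None

    def test_chronic_without_production_or_headroom_is_zero(self):
        params = vf.fixture("fig4_chronic").replace(alpha=0.0)
        report = vf.r0_numeric(vf.build_ngm("chronic", params, params.K))
        assert report.total == pytest.approx(0.0, abs=1e-12)


class TestReductionChain:
    def test_implicit_fully_lytic_equals_lytic_closed_form(self, rng):
        for _ in range(100):
            base = sample_parameters("lytic", rng)
            S = rng.uniform(0.0, base.K)
            latent = vf.LatentImplicitParameters(
                b=base.b, b_prime=base.b_prime, K=base.K, phi=base.phi,
                d=base.d, d_prime=base.d_prime, beta=base.beta,
                m=base.m, eta=base.eta, p=1.0, q=0.0)
            got = vf.r0_latent_implicit_closed(latent, S)
            want = vf.r0_lytic_closed(base, S)
            assert got.total == pytest.approx(want.total, rel=1e-12)
            assert got.vertical == 0.0

    def test_pure_lysogeny_equals_explicit_vertical_branch(self, rng):
        for _ in range(100):
            base = sample_parameters("lytic", rng)
            if base.d_prime == 0.0:
                continue
            S = rng.uniform(0.0, base.K)
            implicit = vf.LatentImplicitParameters(
                b=base.b, b_prime=base.b_prime, K=base.K, phi=base.phi,
                d=base.d, d_prime=base.d_prime, beta=base.beta,
                m=base.m, eta=base.eta, p=0.0, q=1.0)
            explicit = vf.LatentExplicitParameters(
                b=base.b, b_prime=base.b_prime, K=base.K, phi=base.phi,
                d=base.d, d_prime=base.d_prime, beta=base.beta,
                m=base.m, eta=base.eta, q_l=1.0, gamma=0.0)
            lysogen_ratio = base.b_prime / base.d_prime * (1.0 - S / base.K)
            got_implicit = vf.r0_latent_implicit_closed(implicit, S).total
            got_explicit = vf.r0_latent_explicit_closed(explicit, S).total
            assert got_implicit == pytest.approx(lysogen_ratio, rel=1e-12)
            assert got_explicit == pytest.approx(lysogen_ratio, rel=1e-12)


class TestVerticalIdentity:
    def test_life_history_ratio(self):
        params = vf.LatentImplicitParameters(
            b=1.0, b_prime=0.54, K=7.5e7, phi=6.7e-10, d=0.2, d_prime=0.44,
            beta=50.0, m=0.04, eta=1.0, p=0.0, q=1.0)
        value = vf.r0_vertical_identity(params)
        assert value == pytest.approx((0.54 / 0.44) / (1.0 / 0.2), rel=1e-14)
        # equals the vertical component at the virus-free equilibrium
        S_star = params.virus_free_equilibrium()
        report = vf.r0_latent_implicit_closed(params, S_star)
        assert value == pytest.approx(report.vertical, rel=1e-12)

    def test_neutral_life_history_gives_one(self):
        params = vf.LatentImplicitParameters(
            b=1.0, b_prime=1.0, K=7.5e7, phi=6.7e-10, d=0.2, d_prime=0.2,
            beta=50.0, m=0.04, eta=1.0, p=0.0, q=1.0)
        assert vf.r0_vertical_identity(params) == pytest.approx(1.0, rel=1e-14)

    def test_invariant_under_common_scaling_of_infected_rates(self):
        params = vf.LatentImplicitParameters(
            b=1.0, b_prime=0.54, K=7.5e7, phi=6.7e-10, d=0.2, d_prime=0.44,
            beta=50.0, m=0.04, eta=1.0, p=0.0, q=1.0)
        scaled = params.replace(b_prime=0.54 * 3.7, d_prime=0.44 * 3.7)
        assert (vf.r0_vertical_identity(scaled)
                == pytest.approx(vf.r0_vertical_identity(params), rel=1e-12))


def test_spectral_gap_positive_for_distinct_modes(lytic_params):
    assert spectral_gap(vf.build_ngm("lytic", lytic_params, 1e7)) > 0.0
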