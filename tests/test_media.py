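"""Debye media: evaluation, fitting, unit bridges, material library."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwtomo.media import (
    MATERIALS,
    DebyeFitError,
    DebyeMedium,
    DispersionTable,
    eps2_from_sigma,
    eval_debye,
    fit_debye,
    load_material_library,
    save_material_library,
    sigma_from_eps2,
)

GHZ = 1e9


class TestEvalDebye:
    def test_dispersionless_limit(self):
        m = DebyeMedium(eps_inf=5.0, delta_eps=0.0, tau=1e-11, sigma_s=0.0)
        for f in (0.6e9, 1.2e9, 3.3e9):
            assert eval_debye(m, f) == pytest.approx(5.0 + 0j)

    def test_pole_identity_at_omega_tau_one(self):
        # at omega*tau = 1 the pole contributes delta_eps/2 to both parts
        tau = 70e-12
        f = 1.0 / (2 * np.pi * tau)
        m = DebyeMedium(eps_inf=4.0, delta_eps=10.0, tau=tau, sigma_s=0.0)
        eps = eval_debye(m, f)
        assert eps.real == pytest.approx(4.0 + 5.0)
        assert -eps.imag == pytest.approx(5.0)

    def test_rejects_nonpositive_frequency(self):
        m = DebyeMedium(eps_inf=2.0)
        with pytest.raises(ValueError):
            eval_debye(m, 0.0)
        with pytest.raises(ValueError):
            eval_debye(m, -1e9)

    def test_loss_sign_convention(self):
        m = MATERIALS["glycerine_water_90"]
        eps = m.eval(1.5e9)
        assert eps.imag < 0  # eps' - j eps'' with eps'' > 0

    @given(
        eps_inf=st.floats(1.0, 50.0),
        delta_eps=st.floats(0.0, 80.0),
        tau_ps=st.floats(1.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_real_part_nonincreasing_without_conductivity(self, eps_inf, delta_eps, tau_ps):
        m = DebyeMedium(eps_inf=eps_inf, delta_eps=delta_eps, tau=tau_ps * 1e-12)
        f = np.linspace(0.3e9, 4.0e9, 40)
        real = eval_debye(m, f).real
        assert np.all(np.diff(real) <= 1e-12)


class TestFixtureMaterials:
    """Shipped media anchor exactly to the measured 1.2 GHz values."""

    @pytest.mark.parametrize(
        "name, eps1, eps2",
        [
            ("water", 78.6, 4.8),
            ("salt_water_10mgml", 77.5, 30.5),
            ("glycerine_water_90", 14.2, 13.3),
        ],
    )
    def test_anchor_values(self, name, eps1, eps2):
        eps = MATERIALS[name].eval(1.2 * GHZ)
        assert eps.real == pytest.approx(eps1, abs=1e-6)
        assert -eps.imag == pytest.approx(eps2, abs=1e-6)

    def test_library_json_round_trip(self, tmp_path):
        path = tmp_path / "materials.json"
        save_material_library(path)
        lib = load_material_library(path)
        assert set(lib) == set(MATERIALS)
        for name in MATERIALS:
            assert lib[name].eval(1.5e9) == pytest.approx(MATERIALS[name].eval(1.5e9))


class TestSigmaEps2Bridge:
    def test_zero_loss_maps_to_zero_conductivity(self):
        assert sigma_from_eps2(0.0, 2.2e9) == 0.0

    def test_round_trip(self):
        s = eps2_from_sigma(1.0, 1.5e9)
        assert sigma_from_eps2(s, 1.5e9) == pytest.approx(1.0, rel=1e-14)

    def test_hand_computed_value(self):
        # sigma = 2 pi f eps0 eps'': f = 1.0 GHz, eps'' = 10
        expected = 2 * np.pi * 1.0e9 * 8.8541878128e-12 * 10.0
        assert sigma_from_eps2(10.0, 1.0e9) == pytest.approx(expected, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sigma_from_eps2(-1.0, 1e9)
        with pytest.raises(ValueError):
            eps2_from_sigma(1.0, 0.0)


class TestFitDebye:
    def _table_from(self, medium, freqs):
        return DispersionTable(freqs=freqs, eps_complex=eval_debye(medium, freqs))

    def test_round_trip_recovers_parameters(self):
        truth = DebyeMedium(eps_inf=6.0, delta_eps=20.0, tau=60e-12, sigma_s=0.4)
        freqs = np.linspace(0.5e9, 3.5e9, 8)
        fitted, diag = fit_debye(self._table_from(truth, freqs))
        assert diag.residual_norm < 1e-6
        assert fitted.eps_inf == pytest.approx(truth.eps_inf, rel=0.01)
        assert fitted.delta_eps == pytest.approx(truth.delta_eps, rel=0.01)
        assert fitted.tau == pytest.approx(truth.tau, rel=0.01)
        assert fitted.sigma_s == pytest.approx(truth.sigma_s, rel=0.01)

    def test_constant_table_is_dispersionless(self):
        freqs = np.linspace(0.5e9, 3.0e9, 6)
        table = DispersionTable(freqs=freqs, eps_complex=np.full(6, 10.0 + 0j))
        fitted, _ = fit_debye(table)
        assert fitted.eps_inf + fitted.delta_eps / 1e3 == pytest.approx(10.0, abs=0.05)
        assert fitted.delta_eps == pytest.approx(0.0, abs=0.05)
        assert fitted.sigma_s == pytest.approx(0.0, abs=1e-3)

    def test_noisy_table_recovery_within_5pct(self):
        """With 1% multiplicative noise the ensemble-mean fitted parameters
        stay within 5% of truth and each draw reproduces the true dispersion
        curve within 5% (eps_inf alone is the small term of a large sum, so
        only its ensemble mean — not every single draw — is identifiable to
        5% at this noise level)."""
        truth = DebyeMedium(eps_inf=8.0, delta_eps=30.0, tau=40e-12, sigma_s=0.6)
        freqs = np.linspace(0.5e9, 3.5e9, 10)
        clean = eval_debye(truth, freqs)
        rng = np.random.default_rng(42)
        fits = []
        for _ in range(20):
            noisy = clean * (1.0 + 0.01 * rng.standard_normal(len(freqs)))
            noisy = np.clip(noisy.real, 1.0, None) + 1j * np.minimum(noisy.imag, 0.0)
            fitted, _ = fit_debye(DispersionTable(freqs=freqs, eps_complex=noisy))
            curve_err = np.max(
                np.abs(eval_debye(fitted, freqs) - clean) / np.abs(clean)
            )
            assert curve_err < 0.05
            fits.append([fitted.eps_inf, fitted.delta_eps, fitted.tau, fitted.sigma_s])
        mean = np.mean(fits, axis=0)
        tv = [truth.eps_inf, truth.delta_eps, truth.tau, truth.sigma_s]
        rel = [abs(a - b) / b for a, b in zip(mean, tv)]
        assert max(rel) < 0.05, rel

    def test_glycerine_fixture_refit_reproduces_anchor(self):
        """A fit to the fixture's own dispersion curve reproduces the 1.2 GHz
        anchor within 5%."""
        truth = MATERIALS["glycerine_water_90"]
        freqs = np.linspace(0.5e9, 3.5e9, 8)
        fitted, _ = fit_debye(self._table_from(truth, freqs))
        eps = fitted.eval(1.2e9)
        assert eps.real == pytest.approx(14.2, rel=0.05)
        assert -eps.imag == pytest.approx(13.3, rel=0.05)

    def test_insufficient_data_errors(self):
        freqs = np.array([1.0e9, 2.0e9])
        with pytest.raises(DebyeFitError):
            fit_debye(DispersionTable(freqs=freqs, eps_complex=np.full(2, 5.0 + 0j)))
        narrow = np.linspace(1.0e9, 1.5e9, 5)
        with pytest.raises(DebyeFitError):
            fit_debye(DispersionTable(freqs=narrow, eps_complex=np.full(5, 5.0 + 0j)))

    def test_fit_is_deterministic(self):
        truth = DebyeMedium(eps_inf=6.0, delta_eps=20.0, tau=60e-12, sigma_s=0.4)
        freqs = np.linspace(0.5e9, 3.5e9, 8)
        t = self._table_from(truth, freqs)
        m1, _ = fit_debye(t)
        m2, _ = fit_debye(t)
        assert m1 == m2


class TestDispersionTable:
    def test_csv_round_trip(self, tmp_path):
        freqs = np.linspace(0.5e9, 3.5e9, 5)
        t = DispersionTable(freqs=freqs, eps_complex=eval_debye(MATERIALS["water"], freqs))
        path = tmp_path / "disp.csv"
        t.to_csv(path)
        t2 = DispersionTable.from_csv(path)
        np.testing.assert_allclose(t2.freqs, t.freqs)
        np.testing.assert_allclose(t2.eps_complex, t.eps_complex, rtol=1e-12)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            DispersionTable(freqs=np.array([2e9, 1e9, 3e9]), eps_complex=np.full(3, 5.0 + 0j))
        with pytest.raises(ValueError):
            DispersionTable(freqs=np.array([1e9, 2e9]), eps_complex=np.array([5.0 + 1j, 5.0 + 0j]))


def test_medium_invariants_enforced():
    with pytest.raises(ValueError):
        DebyeMedium(eps_inf=0.5)
    with pytest.raises(ValueError):
        DebyeMedium(eps_inf=2.0, delta_eps=-1.0)
    with pytest.raises(ValueError):
        DebyeMedium(eps_inf=2.0, tau=0.0)
    with pytest.raises(ValueError):
        DebyeMedium(eps_inf=2.0, sigma_s=-0.1)
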