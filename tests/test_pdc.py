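"""MVAR fitting, transfer functions, and partial directed coherence."""

import numpy as np
import pandas as pd
import pytest

from myocortex import MvarModel, band_pdc, fit_mvar, gen_mvar_data, pdc, pdc_contrast, transfer_function
from myocortex.pdc_mvar import MvarError, companion_spectral_radius, spectral_abar

A_BIVARIATE = np.array([[[0.5, 0.0], [0.4, 0.5]], [[-0.2, 0.0], [0.0, -0.2]]])


class TestFitMvar:
    def test_known_bivariate_recovery(self):
        rec = gen_mvar_data(A_BIVARIATE, n_samples=20_000, seed=0)
        model = fit_mvar(rec.data, rate=500.0, max_order=6)
        assert model.order == 2
        assert np.abs(model.coefs - A_BIVARIATE).max() < 0.05
        assert model.stable

    def test_white_noise_forced_order(self, rng):
        x = rng.standard_normal((2, 20_000))
        model = fit_mvar(x, rate=500.0, order=3)
        assert np.abs(model.coefs).max() < 0.05

    def test_bic_selects_true_order(self):
        hits = 0
        for seed in range(10):
            rec = gen_mvar_data(np.array([[[1.2]], [[-0.5]]]), n_samples=4000, seed=seed)
            hits += fit_mvar(rec.data, rate=500.0, max_order=8).order == 2
        assert hits >= 9

    def test_too_short_series_refused(self, rng):
        with pytest.raises(MvarError):
            fit_mvar(rng.standard_normal((3, 20)), rate=500.0, order=10)


class TestTransferFunction:
    def test_no_dynamics_identity(self):
        model = MvarModel(np.zeros((1, 3, 3)), np.eye(3), 500.0)
        h = transfer_function(model, np.array([0.0, 10.0, 100.0]))
        assert np.allclose(h, np.eye(3)[None, :, :])

    def test_univariate_dc_closed_form(self):
        # AR(1) a=0.5: H(0) = 1 / (1 - 0.5) = 2
        model = MvarModel(np.array([[[0.5]]]), np.eye(1), 500.0)
        h = transfer_function(model, np.array([0.0]))
        assert h[0, 0, 0] == pytest.approx(2.0)

    def test_lower_triangular_coefs_give_lower_triangular_h(self):
        a = np.array([[[0.5, 0.0, 0.0], [0.3, 0.4, 0.0], [0.1, 0.2, 0.3]]])
        model = MvarModel(a, np.eye(3), 500.0)
        h = transfer_function(model, np.arange(1.0, 100.0, 7.0))
        assert np.allclose(h[:, 0, 1], 0.0) and np.allclose(h[:, 0, 2], 0.0)
        assert np.allclose(h[:, 1, 2], 0.0)

    def test_unstable_model_refused(self):
        model = MvarModel(np.array([[[1.1]]]), np.eye(1), 500.0)
        with pytest.raises(MvarError):
            transfer_function(model, np.array([10.0]))


class TestPdc:
    def test_diagonal_model_no_cross_pdc(self):
        model = MvarModel(np.array([[[0.5, 0.0], [0.0, 0.3]]]), np.eye(2), 500.0)
        for variant in ("H", "Abar"):
            spec = pdc(model, variant=variant)
            assert np.allclose(spec.values[:, 0, 1], 0.0)
            assert np.allclose(spec.values[:, 1, 0], 0.0)

    def test_column_normalization_exact(self):
        rec = gen_mvar_data(A_BIVARIATE, n_samples=5000, seed=1)
        model = fit_mvar(rec.data, rate=500.0, max_order=6)
        spec = pdc(model)
        sums = spec.values.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-10

    def test_unidirectional_coupling_directionality(self):
        a1 = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        model = MvarModel(a1, np.eye(2), 500.0)
        spec = pdc(model, np.array([10.0]))
        assert spec.values[0, 1, 0] > 0.01   # 1 -> 2 present
        assert spec.values[0, 0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_10hz(self):
        """H-normalised PDC for A1=[[0.5,0],[0.4,0.5]] at f=10 Hz, rate 500:
        H = Abar^-1 computed independently with explicit 2x2 inversion."""
        a1 = np.array([[0.5, 0.0], [0.4, 0.5]])
        f, rate = 10.0, 500.0
        z = np.exp(-2j * np.pi * f / rate)
        abar = np.eye(2) - a1 * z
        det = abar[0, 0] * abar[1, 1] - abar[0, 1] * abar[1, 0]
        h = np.array([[abar[1, 1], -abar[0, 1]], [-abar[1, 0], abar[0, 0]]]) / det
        mag2 = np.abs(h) ** 2
        expected = mag2 / mag2.sum(axis=0, keepdims=True)
        model = MvarModel(a1[None, :, :], np.eye(2), rate)
        spec = pdc(model, np.array([f]))
        assert np.allclose(spec.values[0], expected, atol=1e-12)

    def test_values_bounded(self):
        rec = gen_mvar_data(A_BIVARIATE, n_samples=5000, seed=2)
        model = fit_mvar(rec.data, rate=500.0, max_order=6)
        for variant in ("H", "Abar"):
            v = pdc(model, variant=variant).values
            assert v.min() >= 0.0 and v.max() <= 1.0 + 1e-12

    def test_abar_variant_matches_direct_formula(self):
        model = MvarModel(A_BIVARIATE, np.eye(2), 500.0)
        freqs = np.array([5.0, 20.0])
        abar = spectral_abar(model, freqs)
        mag2 = np.abs(abar) ** 2
        expected = mag2 / mag2.sum(axis=1, keepdims=True)
        assert np.allclose(pdc(model, freqs, variant="Abar").values, expected)


class TestBandPdc:
    def test_constant_spectrum_band_mean(self):
        model = MvarModel(np.zeros((1, 2, 2)), np.eye(2), 500.0)
        spec = pdc(model)  # H = I everywhere: diagonal 1, off-diagonal 0
        bp = band_pdc(spec, (13.0, 30.0))
        assert np.allclose(np.diag(bp), 1.0) and bp[0, 1] == 0.0

    def test_band_splitting_linearity(self):
        rec = gen_mvar_data(A_BIVARIATE, n_samples=4000, seed=3)
        model = fit_mvar(rec.data, rate=500.0, max_order=4)
        spec = pdc(model, np.arange(30.0, 60.5, 0.5))
        whole = band_pdc(spec, (30.0, 60.0))
        lo = band_pdc(spec, (30.0, 44.5))
        hi = band_pdc(spec, (45.0, 60.0))
        n_lo = ((spec.freqs >= 30) & (spec.freqs <= 44.5)).sum()
        n_hi = ((spec.freqs >= 45) & (spec.freqs <= 60)).sum()
        assert np.allclose(whole, (lo * n_lo + hi * n_hi) / (n_lo + n_hi))

    def test_resonant_coupling_concentrates_in_gamma1(self):
        # oscillatory 1 -> 2 coupling at 45 Hz (rate 500)
        r = 0.9
        diag = 2 * r * np.cos(2 * np.pi * 45 / 500)
        a1 = np.array([[diag, 0.0], [0.3, diag]])
        a2 = np.diag([-(r**2), -(r**2)])
        model = MvarModel(np.stack([a1, a2]), np.eye(2), 500.0)
        spec = pdc(model)
        g1 = band_pdc(spec, (30.0, 60.0))[1, 0]
        g2 = band_pdc(spec, (60.0, 100.0))[1, 0]
        assert g1 > g2

    def test_empty_band_refused(self):
        model = MvarModel(np.zeros((1, 2, 2)), np.eye(2), 500.0)
        spec = pdc(model, np.array([10.0]))
        with pytest.raises(MvarError):
            band_pdc(spec, (40.0, 50.0))


class TestZeroCouplingFloor:
    def test_true_zero_coupling_estimated_below_005(self):
        """Couplings absent from the generator stay below 0.05 in fitted band PDC."""
        a = np.array([[[0.5, 0.0], [0.4, 0.5]], [[-0.2, 0.0], [0.0, -0.2]]])  # no 2->1
        rec = gen_mvar_data(a, n_samples=10_000, seed=5)
        model = fit_mvar(rec.data, rate=500.0, max_order=6)
        spec = pdc(model)
        for band in ((13.0, 30.0), (30.0, 60.0), (60.0, 100.0)):
            assert band_pdc(spec, band)[0, 1] < 0.05


def _band_table(rng, subjects, offset=0.0, pair_offset=None):
    rows = []
    for s in subjects:
        for src, tgt in (("C3", "EMG"), ("C4", "EMG"), ("EMG", "C3"),
                         ("EMG", "C4"), ("C3", "C4"), ("C4", "C3")):
            for band in ("beta", "gamma1", "gamma2"):
                v = 0.3 + 0.02 * rng.standard_normal() + offset
                if pair_offset and (src, tgt, band) in pair_offset:
                    v += pair_offset[(src, tgt, band)]
                rows.append({"subject": s, "source": src, "target": tgt,
                             "band": band, "value": v})
    return pd.DataFrame(rows)


class TestPdcContrast:
    def test_null_contrast_rarely_significant(self, rng):
        subjects = [f"s{i}" for i in range(12)]
        a = _band_table(rng, subjects)
        b = _band_table(rng, subjects)
        out = pdc_contrast(a, b)
        assert out.significant.mean() <= 0.1

    def test_injected_gamma1_increase_flagged(self, rng):
        subjects = [f"s{i}" for i in range(12)]
        b = _band_table(rng, subjects)
        a = _band_table(rng, subjects,
                        pair_offset={("C4", "EMG", "gamma1"): 0.2})
        out = pdc_contrast(a, b)
        hit = out[(out.source == "C4") & (out.target == "EMG") & (out.band == "gamma1")]
        assert bool(hit.significant.iloc[0])
        assert hit.direction.iloc[0] == "increased"

    def test_global_shift_flags_everything(self, rng):
        subjects = [f"s{i}" for i in range(10)]
        b = _band_table(rng, subjects)
        a = _band_table(rng, subjects, offset=0.5)
        out = pdc_contrast(a, b)
        assert out.significant.all()
        assert (out.direction == "increased").all()

    def test_unmatched_subjects_refused(self, rng):
        a = _band_table(rng, ["s1", "s2", "s3"])
        b = _band_table(rng, ["s1", "s2", "s4"])
        with pytest.raises(MvarError):
            pdc_contrast(a, b)
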