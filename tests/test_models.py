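"""Diffusion-model fitting: closed-form reductions, self-consistent
recovery, noise robustness, and failure accounting."""

import numpy as np
import pandas as pd
import pytest

import modemdwi as m
from modemdwi.models import (BOUNDS, ctrw_signal, dki_signal, fit_ctrw,
                             fit_dki, fit_froc, fit_ivim, fit_mono,
                             fits_to_frame, froc_signal, ivim_signal,
                             mono_signal)
from modemdwi.noise import rician_sample


@pytest.fixture(scope="module")
def b13(protocol13):
    return np.array(protocol13.b_values)


class TestMono:
    def test_two_point_adc(self, b13):
        s = np.ones_like(b13)
        s[b13 == 1000.0] = np.exp(-1.0)
        assert fit_mono((b13, s)).adc == pytest.approx(1.0e-3, rel=1e-12)
        assert fit_mono((b13, np.ones_like(b13))).adc == 0.0

    def test_self_consistency(self, b13):
        s = mono_signal(b13, 2.0e-3)
        assert fit_mono((b13, s)).adc == pytest.approx(2.0e-3, rel=1e-12)

    def test_requires_b0_and_b1000(self):
        with pytest.raises(ValueError, match="b = 0 and 1000"):
            fit_mono((np.array([0.0, 500.0]), np.array([1.0, 0.5])))

    def test_nonpositive_signal_raises(self, b13):
        s = np.ones_like(b13)
        s[b13 == 1000.0] = 0.0
        with pytest.raises(ValueError, match="nonpositive"):
            fit_mono((b13, s))


class TestIVIM:
    def test_recovery_on_generating_model(self, b13):
        s = ivim_signal(b13, 0.10, 20e-3, 1.0e-3)
        fit = fit_ivim((b13, s))
        assert fit.f == pytest.approx(0.10, rel=0.05)
        assert fit.d_perf == pytest.approx(20e-3, rel=0.05)
        assert fit.d_diff == pytest.approx(1.0e-3, rel=0.05)
        assert fit.d_perf >= fit.d_diff

    def test_f_zero_degenerates_to_mono(self, b13):
        s = mono_signal(b13, 1.5e-3)
        fit = fit_ivim((b13, s))
        assert fit.f == pytest.approx(0.0, abs=1e-6)
        assert fit.d_diff == pytest.approx(1.5e-3, rel=1e-4)

    def test_identical_rows_identical_fits(self, b13):
        s = ivim_signal(b13, 0.2, 15e-3, 0.8e-3)
        f1, f2 = fit_ivim((b13, s)), fit_ivim((b13, s))
        assert (f1.f, f1.d_perf, f1.d_diff) == (f2.f, f2.d_perf, f2.d_diff)

    def test_needs_points_in_both_segments(self):
        b = np.array([0.0, 1000.0])
        with pytest.raises(ValueError, match="segments"):
            fit_ivim((b, np.array([1.0, 0.3])))


class TestNestedReductions:
    """Each richer model collapses to the mono-exponential at its
    degenerate parameter point, and fits on such data recover it."""

    def test_dki_k_zero(self, b13):
        fit = fit_dki((b13, mono_signal(b13, 1.2e-3)))
        assert fit.d == pytest.approx(1.2e-3, rel=1e-3)
        assert fit.k == pytest.approx(0.0, abs=1e-4)

    def test_froc_beta_one_exponent_equals_b_d(self, b13, protocol13):
        # at beta = 1, (gamma Gd delta)^2 (Delta - delta/3) = b exactly
        s_froc = froc_signal(b13, 1.5e-3, 1.0, 7.0, protocol13)
        assert np.allclose(s_froc, mono_signal(b13, 1.5e-3), rtol=1e-9)
        fit = fit_froc((b13, mono_signal(b13, 1.5e-3)), protocol13)
        assert fit.d * (fit.mu * 1e-6) ** (2 * (fit.beta - 1)) == \
            pytest.approx(1.5e-3, rel=1e-3)
        assert fit.beta == pytest.approx(1.0, abs=1e-3)

    def test_ctrw_alpha_beta_one(self, b13):
        assert np.allclose(ctrw_signal(b13, 1.0e-3, 1.0, 1.0),
                           mono_signal(b13, 1.0e-3), rtol=1e-12)
        fit = fit_ctrw((b13, mono_signal(b13, 1.0e-3)))
        assert fit.d_m == pytest.approx(1.0e-3, rel=1e-3)
        assert fit.alpha == pytest.approx(1.0, abs=1e-3)
        assert fit.beta == pytest.approx(1.0, abs=1e-3)

    def test_ivim_f_zero_signal_equals_mono(self, b13):
        assert np.allclose(ivim_signal(b13, 0.0, 20e-3, 1.0e-3),
                           mono_signal(b13, 1.0e-3), rtol=1e-15)


class TestRecovery:
    def test_ctrw_noiseless_one_percent(self, b13):
        fit = fit_ctrw((b13, ctrw_signal(b13, 1.0e-3, 0.8, 0.9)))
        assert fit.d_m == pytest.approx(1.0e-3, rel=0.01)
        assert fit.alpha == pytest.approx(0.8, rel=0.01)
        assert fit.beta == pytest.approx(0.9, rel=0.01)

    def test_dki_noiseless(self, b13):
        fit = fit_dki((b13, dki_signal(b13, 1.1e-3, 0.8)))
        assert fit.d == pytest.approx(1.1e-3, rel=1e-3)
        assert fit.k == pytest.approx(0.8, rel=1e-3)

    def test_froc_identifiable_combination(self, b13, protocol13):
        """FROC has an exact D-mu ridge at fixed beta; the identifiable
        quantity is D mu^(2 beta - 2) (SI), recovered to high accuracy."""
        true = (1.0e-3, 0.8, 8.0)
        fit = fit_froc((b13, froc_signal(b13, *true, protocol13)), protocol13)
        d_eff_true = true[0] * (true[2] * 1e-6) ** (2 * (true[1] - 1))
        d_eff_fit = fit.d * (fit.mu * 1e-6) ** (2 * (fit.beta - 1))
        assert fit.beta == pytest.approx(0.8, rel=1e-3)
        assert d_eff_fit == pytest.approx(d_eff_true, rel=1e-3)

    @pytest.mark.parametrize("model", ["mono", "ivim", "dki", "froc", "ctrw"])
    def test_median_diffusivity_error_under_one_percent_noise(
            self, model, b13, protocol13):
        """Median relative error of the diffusivity-type parameter < 10%
        at 1% Rician noise on the 13-b grid, 1000 synthetic voxels."""
        rng = np.random.default_rng(2024)
        n = 1000
        errs = np.empty(n)
        for i in range(n):
            d_true = rng.uniform(0.6e-3, 2.2e-3)
            if model == "mono":
                s = mono_signal(b13, d_true)
            elif model == "ivim":
                s = ivim_signal(b13, rng.uniform(0.05, 0.2),
                                rng.uniform(10e-3, 30e-3), d_true)
            elif model == "dki":
                s = dki_signal(b13, d_true, rng.uniform(0.3, 1.2))
            elif model == "froc":
                beta = rng.uniform(0.75, 0.95)
                s = froc_signal(b13, d_true, beta, 8.0, protocol13)
                # identifiable effective diffusivity at the reference b
                d_true = -np.log(
                    froc_signal(np.array([1000.0]), d_true, beta, 8.0,
                                protocol13)[0]) / 1000.0
            else:
                s = ctrw_signal(b13, d_true, rng.uniform(0.75, 0.95),
                                rng.uniform(0.8, 1.0))
            noisy = rician_sample(s, 0.01, 1, rng)[0]
            noisy = noisy / noisy[0]
            if model == "mono":
                d_fit = fit_mono((b13, noisy)).adc
            elif model == "ivim":
                d_fit = fit_ivim((b13, noisy)).d_diff
            elif model == "dki":
                d_fit = fit_dki((b13, noisy)).d
            elif model == "froc":
                f = fit_froc((b13, noisy), protocol13)
                d_fit = -np.log(
                    froc_signal(np.array([1000.0]), f.d, f.beta, f.mu,
                                protocol13)[0]) / 1000.0
            else:
                d_fit = fit_ctrw((b13, noisy)).d_m
            errs[i] = abs(d_fit - d_true) / d_true
        assert np.median(errs) < 0.10


class TestDescentAndBounds:
    def test_residual_never_worse_than_initialization(self, b13):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = ctrw_signal(b13, rng.uniform(0.5e-3, 2e-3),
                            rng.uniform(0.5, 1.0), rng.uniform(0.5, 1.0))
            s = np.clip(s + rng.normal(0, 0.05, s.size), 1e-3, None)
            s[0] = 1.0
            adc0 = np.clip(np.log(s[0] / s[b13 == 1000.0][0]) / 1000.0,
                           *BOUNDS["d"])
            init_res = np.linalg.norm(ctrw_signal(b13, adc0, 1.0, 1.0) - s)
            fit = fit_ctrw((b13, s))
            assert fit.residual_norm <= init_res + 1e-12

    def test_fitted_parameters_respect_bounds(self, cellsize_table,
                                              protocol13):
        sub = cellsize_table.iloc[:10]
        for fit in m.fit_table(sub, "dki"):
            assert BOUNDS["d"][0] <= fit.d <= BOUNDS["d"][1]
            assert BOUNDS["k"][0] <= fit.k <= BOUNDS["k"][1]
        ctrw_fits = [f for f in m.fit_table(sub, "ctrw") if f.converged]
        assert len(ctrw_fits) == len(sub)  # all rows should fit cleanly
        for fit in ctrw_fits:
            assert 0 < fit.alpha <= 1 and 0 < fit.beta <= 1


class TestFitTable:
    def test_rowwise_counts(self, cellsize_table):
        sub = cellsize_table.iloc[:3]
        fits = m.fit_table(sub, "mono")
        assert len(fits) == 3
        assert m.fit_table(cellsize_table.iloc[:0], "mono") == []

    def test_pathological_row_flagged_not_raised(self, b13):
        good = mono_signal(b13, 1.0e-3)
        bad = np.zeros_like(b13)  # S(1000) = 0 defeats the ADC estimate
        table = pd.DataFrame([good, bad],
                             columns=[f"b_{bv:g}" for bv in b13])
        fits = m.fit_table(table, "mono")
        assert fits[0].converged and np.isfinite(fits[0].adc)
        assert not fits[1].converged and np.isnan(fits[1].adc)
        frame = fits_to_frame(fits, "mono")
        assert list(frame["converged"]) == [True, False]
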