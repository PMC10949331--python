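import numpy as np
import pytest

from gelkit.io import Spectrum, ValidationError
from gelkit.spectro import (
    AmideBandModel,
    ThermalMeltModel,
    band_area,
    cd_deconvolve,
    fraction_helix,
    ftir_band_decompose,
    hdx_kinetics,
    melt_analysis,
    mre_coil,
    mre_convert,
    synthetic_basis_spectra,
)
from gelkit.synth import GeneratorSpec, generate


class TestMreConvert:
    def test_zero_signal_maps_to_zero(self):
        s = Spectrum([200.0, 222.0], [0.0, 0.0])
        assert np.all(mre_convert(s, 0.1, 0.1, 100).signal == 0.0)

    def test_direct_evaluation(self):
        s = Spectrum([222.0, 223.0], [10.0, 10.0])
        out = mre_convert(s, c_mM=0.1, l_cm=0.1, n_bonds=100)
        np.testing.assert_allclose(out.signal, 1000.0)

    def test_linearity_in_concentration(self, rng):
        y = rng.normal(size=5)
        s = Spectrum(np.arange(5.0), y)
        half = mre_convert(s, 0.2, 0.1, 100).signal
        np.testing.assert_allclose(mre_convert(s, 0.1, 0.1, 100).signal, 2 * half)

    def test_invalid_parameters(self):
        s = Spectrum([222.0, 223.0], [1.0, 1.0])
        with pytest.raises(ValidationError):
            mre_convert(s, 0.0, 0.1, 100)


class TestFractionHelix:
    def test_coil_baseline_gives_zero(self):
        assert fraction_helix(mre_coil(25.0), 25.0, 228) == pytest.approx(0.0)

    def test_full_helix_gives_100(self):
        n = 228
        assert fraction_helix(-42500 * (1 - 3 / n), 25.0, n) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        # (-20000 - (640-225)) / (-42500*(1-3/228) - (640-225)) * 100
        assert fraction_helix(-20000.0, 5.0, 228) == pytest.approx(48.2, abs=0.05)

    def test_affine_in_mre(self):
        vals = [fraction_helix(m, 25.0, 228) for m in (-10000, -20000, -30000)]
        assert vals[1] - vals[0] == pytest.approx(vals[2] - vals[1])

    def test_small_bond_count_rejected(self):
        with pytest.raises(ValidationError):
            fraction_helix(-20000, 25.0, 3)


class TestDeconvolution:
    def test_exact_mixture_recovered(self):
        basis = synthetic_basis_spectra()
        wl = basis["helix"].abscissa
        mix = 0.3 * basis["helix"].signal + 0.2 * basis["sheet"].signal + 0.5 * basis["coil"].signal
        fr = cd_deconvolve(Spectrum(wl, mix), basis)
        assert fr["helix"] == pytest.approx(0.3, abs=1e-9)
        assert fr["sheet"] == pytest.approx(0.2, abs=1e-9)
        assert fr["coil"] == pytest.approx(0.5, abs=1e-9)

    def test_pure_basis_spectrum(self):
        basis = synthetic_basis_spectra()
        fr = cd_deconvolve(basis["helix"], basis)
        assert fr["helix"] == pytest.approx(1.0, abs=1e-9)
        assert fr["sheet"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        errs = {"helix": [], "sheet": [], "coil": []}
        for seed in range(100):
            out = generate(GeneratorSpec("cd_mixture", seed=seed, noise={"kind": "gaussian_abs", "level": 400.0}))
            fr = cd_deconvolve(out["data"]["spectrum"], out["data"]["basis"])
            truth = out["truth"]["params"]
            for name in errs:
                errs[name].append(fr[name] - truth[name])
        for name, e in errs.items():
            assert abs(np.mean(e)) < 0.05, name

    def test_simplex_mode_sums_to_one(self):
        basis = synthetic_basis_spectra()
        wl = basis["helix"].abscissa
        mix = 0.6 * basis["helix"].signal + 0.4 * basis["coil"].signal
        fr = cd_deconvolve(Spectrum(wl, mix * 1.1), basis, simplex=True)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(v >= -1e-12 for v in fr.values())

    def test_rank_deficient_basis_rejected(self):
        basis = synthetic_basis_spectra()
        degenerate = {"a": basis["helix"], "b": basis["helix"]}
        with pytest.raises(ValidationError):
            cd_deconvolve(basis["helix"], degenerate)


class TestMelt:
    def test_recovers_midpoint_from_synthetic_two_state(self):
        out = generate(
            GeneratorSpec("cd_melt", seed=1, noise={"kind": "gaussian_abs", "level": 100.0})
        )
        res = melt_analysis(out["data"]["heating"], out["data"]["cooling"])
        assert res.heating.tm == pytest.approx(37.0, abs=0.5)
        assert res.cooling.tm == pytest.approx(37.0, abs=0.5)

    def test_identical_ramps_have_zero_hysteresis(self):
        out = generate(GeneratorSpec("cd_melt", seed=2, noise={"kind": "gaussian_abs", "level": 0.0}))
        T, y = out["data"]["heating"]
        res = melt_analysis((T, y), (T, y))
        assert res.hysteresis == pytest.approx(0.0, abs=1e-6)

    def test_monotone_line_is_flagged(self):
        T = np.linspace(5, 90, 50)
        fit = ThermalMeltModel(T, -5000.0 + 10.0 * T).fit()
        assert fit.flagged
        assert fit.tm is None

    def test_midpoint_recovery_across_range(self):
        # bias < 0.5 degC across melts spanning the low/high midpoint regimes
        biases = []
        for i, tm in enumerate(np.linspace(15, 60, 10)):
            out = generate(
                GeneratorSpec(
                    "cd_melt",
                    params={"tm": float(tm)},
                    seed=40 + i,
                    noise={"kind": "gaussian_abs", "level": 150.0},
                )
            )
            res = ThermalMeltModel(*out["data"]["heating"]).fit()
            biases.append(res.tm - tm)
        assert abs(np.mean(biases)) < 0.5


class TestAmideBands:
    def test_noiseless_three_gaussian_recovery(self):
        out = generate(GeneratorSpec("ftir_amide", seed=1, noise={"kind": "gaussian_abs", "level": 0.0}))
        fit = ftir_band_decompose(out["data"]["spectrum"])
        truth = out["truth"]["params"]
        for name, c_true, f_true in zip(
            ("beta_low", "unordered", "beta_high"), truth["centers"], truth["area_fractions"]
        ):
            assert fit.bands[name]["center"] == pytest.approx(c_true, abs=0.5)
            assert fit.fractions[name] == pytest.approx(f_true, rel=0.02)

    def test_fractional_areas_sum_to_one(self):
        out = generate(GeneratorSpec("ftir_amide", seed=2))
        fit = ftir_band_decompose(out["data"]["spectrum"])
        assert sum(fit.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_gaussian_second_derivative_minimum_at_center(self):
        from gelkit.spectro import _derivative_seeds

        x = np.arange(1600.0, 1701.0, 0.5)
        y = np.exp(-0.5 * ((x - 1646.0) / 6.0) ** 2)
        seeds = _derivative_seeds(Spectrum(x, y), {"unordered": (1640.0, 1652.0)})
        assert seeds["unordered"] == pytest.approx(1646.0, abs=0.5)

    def test_centers_constrained_to_windows(self):
        out = generate(GeneratorSpec("ftir_amide", seed=3))
        fit = ftir_band_decompose(out["data"]["spectrum"])
        from gelkit.spectro import AMIDE_WINDOWS

        for name, (lo, hi) in AMIDE_WINDOWS.items():
            assert lo <= fit.bands[name]["center"] <= hi

    def test_baseline_invariance_when_baseline_fit(self):
        out = generate(GeneratorSpec("ftir_amide", seed=4, noise={"kind": "gaussian_abs", "level": 0.0}))
        spec = out["data"]["spectrum"]
        tilted = Spectrum(spec.abscissa, spec.signal + 0.05 + 1e-4 * (spec.abscissa - 1650))
        f1 = ftir_band_decompose(spec).fractions
        f2 = ftir_band_decompose(tilted).fractions
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-3)

    def test_spectrum_not_covering_band_rejected(self):
        x = np.arange(1630.0, 1660.0, 0.5)
        with pytest.raises(ValidationError):
            AmideBandModel(Spectrum(x, np.ones_like(x)))


class TestHdx:
    def test_flat_spectrum_has_zero_band_area(self):
        x = np.arange(1380.0, 1721.0, 0.5)
        assert band_area(Spectrum(x, np.ones_like(x)), (1400.0, 1500.0)) == pytest.approx(0.0)

    def test_exchange_rate_recovered_within_five_percent(self):
        out = generate(GeneratorSpec("hdx", seed=5, noise={"kind": "gaussian_abs", "level": 0.001}))
        trace, fit = hdx_kinetics(out["data"]["spectra"], out["data"]["times"], fit_exponential=True)
        assert fit["k"] == pytest.approx(out["truth"]["params"]["k_per_min"], rel=0.05)
        assert np.all(np.diff(trace.y) > -0.05)  # growth toward the plateau

    def test_normalization_invariant_to_global_scaling(self):
        out = generate(GeneratorSpec("hdx", seed=6, noise={"kind": "gaussian_abs", "level": 0.0}))
        spectra = out["data"]["spectra"]
        scaled = [Spectrum(s.abscissa, 3.7 * s.signal, dict(s.meta)) for s in spectra]
        t1, _ = hdx_kinetics(spectra, out["data"]["times"])
        t2, _ = hdx_kinetics(scaled, out["data"]["times"])
        np.testing.assert_allclose(t1.y, t2.y, rtol=1e-9)
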