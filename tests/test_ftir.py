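"""FTIR baseline handling, Gaussian deconvolution, populations and trends."""

import dataclasses
import math

import numpy as np
import pytest

import mesokit as mk
from mesokit.ftir import REGIONS, BandModel, subtract_baseline


def make_spectrum(x, y, T=30.0):
    return mk.FTIRSpectrum(np.asarray(x, float), np.asarray(y, float), T)


def gaussians(x, comps):
    y = np.zeros_like(x)
    for a, c, w in comps:
        y = y + a * np.exp(-0.5 * ((x - c) / w) ** 2)
    return y


# ---------------------------------------------------------------------------
# baseline


def test_flat_spectrum_corrects_to_zero():
    x = np.arange(1680.0, 1781.0, 1.0)
    curve = subtract_baseline(make_spectrum(x, np.full_like(x, 0.7)),
                              REGIONS["carbonyl"])
    np.testing.assert_allclose(curve.absorbance, 0.0, atol=1e-12)


def test_pure_linear_ramp_corrects_to_zero():
    x = np.arange(1680.0, 1781.0, 1.0)
    curve = subtract_baseline(make_spectrum(x, 0.1 + 0.002 * (x - 1680)),
                              REGIONS["carbonyl"])
    np.testing.assert_allclose(curve.absorbance, 0.0, atol=1e-12)


def test_gaussian_on_ramp_recovered_to_1e6():
    x = np.arange(1650.0, 1811.0, 0.5)
    pure = gaussians(x, [(1.0, 1730.0, 8.0)])
    spec = make_spectrum(x, pure + 0.05 + 0.001 * (x - 1650))
    curve = subtract_baseline(spec, REGIONS["carbonyl"], clip=False)
    xs, _ = spec.window(*REGIONS["carbonyl"].window)
    np.testing.assert_allclose(curve.absorbance, gaussians(xs, [(1.0, 1730.0, 8.0)]),
                               atol=1e-6)


def test_baseline_subtraction_is_idempotent():
    rng = np.random.default_rng(1)
    x = np.arange(3100.0, 3701.0, 2.0)
    y = gaussians(x, [(0.5, 3400.0, 80.0)]) + 0.02 + 1e-5 * x
    y = y * (1 + 0.005 * rng.standard_normal(x.size))
    once = subtract_baseline(make_spectrum(x, y), REGIONS["oh_stretch"], clip=False)
    twice = subtract_baseline(make_spectrum(once.wavenumber, once.absorbance),
                              REGIONS["oh_stretch"], clip=False)
    np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)


def test_region_outside_grid_rejected():
    x = np.arange(2000.0, 3000.0, 2.0)
    with pytest.raises(ValueError, match="outside"):
        subtract_baseline(make_spectrum(x, np.ones_like(x)), REGIONS["oh_stretch"])


# ---------------------------------------------------------------------------
# band fitting


def test_single_gaussian_recovered_exactly():
    x = np.arange(1650.0, 1811.0, 1.0)
    y = gaussians(x, [(1.0, 1730.0, 9.0)])
    region = dataclasses.replace(REGIONS["carbonyl"],
                                 component_labels=("CO",),
                                 init_centers=(1730.0,), init_widths=(9.0,))
    fit = mk.fit_band(make_spectrum(x, y), region, seed=0)
    c = fit.components[0]
    assert c.center == pytest.approx(1730.0, abs=1e-4)
    assert c.width == pytest.approx(9.0, abs=1e-4)
    assert fit.resid_rms < 1e-6


def test_carbonyl_doublet_centres_within_one_wavenumber():
    """Two Gaussians 11 cm^-1 apart (sigma 8) at SNR 100."""
    rng = np.random.default_rng(4)
    x = np.arange(1650.0, 1811.0, 1.0)
    y = gaussians(x, [(1.0, 1725.0, 8.0), (0.8, 1736.0, 8.0)])
    y = y + rng.normal(0.0, 1.0 / 100.0, x.size)
    fit = mk.fit_band(make_spectrum(x, np.maximum(y, 0)), "carbonyl", seed=4)
    assert fit.component("CO_bonded").center == pytest.approx(1725.0, abs=1.0)
    assert fit.component("CO_free").center == pytest.approx(1736.0, abs=1.0)


def test_oh_triplet_centres_and_areas_recovered(ftir_series):
    sc = mk.m70_w30(seed=6)
    series = ftir_series["M70"]
    spec = min(series, key=lambda s: abs(s.temperature - 30.0))
    fit = mk.fit_band(spec, "oh_stretch", seed=6)
    truth = {c.label: c for c in sc.ftir_components(spec.temperature)
             if c.label.startswith("OH")}
    for label, want in truth.items():
        got = fit.component(label)
        assert got.center == pytest.approx(want.center, abs=5.0), label
        assert got.area == pytest.approx(want.area, rel=0.05), label


def test_adding_a_component_never_raises_the_objective():
    rng = np.random.default_rng(11)
    x = np.arange(1650.0, 1811.0, 1.0)
    y = gaussians(x, [(1.0, 1725.0, 8.0), (0.8, 1736.0, 8.0)])
    y = np.maximum(y + rng.normal(0, 0.01, x.size), 0)
    spec = make_spectrum(x, y)
    one = dataclasses.replace(REGIONS["carbonyl"], component_labels=("CO",),
                              init_centers=(1730.0,), init_widths=(8.0,))
    fit1 = mk.fit_band(spec, one, seed=11)
    fit2 = mk.fit_band(spec, "carbonyl", seed=11)
    assert fit2.resid_rms <= fit1.resid_rms + 1e-12


@pytest.mark.parametrize("sep_sigma", [1.5, 2.0, 3.0])
def test_centre_recovery_bias_below_two_wavenumbers(sep_sigma):
    """Separations >= 1.5 sigma at SNR >= 50, seeded replicates."""
    sigma = 8.0
    c1 = 1715.0
    c2 = c1 + sep_sigma * sigma
    x = np.arange(1650.0, 1811.0, 1.0)
    biases = []
    for s in range(5):
        rng = np.random.default_rng(100 + s)
        y = gaussians(x, [(1.0, c1, sigma), (0.9, c2, sigma)])
        y = np.maximum(y + rng.normal(0, 1.0 / 50.0, x.size), 0)
        region = dataclasses.replace(
            REGIONS["carbonyl"], component_labels=("lo", "hi"),
            init_centers=(c1, c2), init_widths=(sigma, sigma))
        fit = mk.fit_band(make_spectrum(x, y), region, seed=s)
        biases.append([abs(fit.component("lo").center - c1),
                       abs(fit.component("hi").center - c2)])
    assert np.all(np.mean(biases, axis=0) < 2.0)


# ---------------------------------------------------------------------------
# water fractions


def equal_area_fit():
    comps = [mk.BandComponent(lbl, c, w, 1.0 / (w * math.sqrt(2 * math.pi)))
             for lbl, c, w in (("OH_strong", 3300.0, 80.0),
                               ("OH_less", 3450.0, 70.0),
                               ("OH_weak", 3600.0, 50.0))]
    from mesokit.ftir import BandFitResult
    return BandFitResult(REGIONS["oh_stretch"], comps, (0.0, 0.0), 0.0)


def test_equal_areas_give_one_third_each():
    wf = mk.water_fractions(equal_area_fit())
    for phi in (wf.phi_strong, wf.phi_less, wf.phi_weak):
        assert phi == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_single_nonzero_component_takes_all():
    from mesokit.ftir import BandFitResult
    comps = [mk.BandComponent("OH_strong", 3300.0, 80.0, 1.0),
             mk.BandComponent("OH_less", 3450.0, 70.0, 0.0),
             mk.BandComponent("OH_weak", 3600.0, 50.0, 0.0)]
    wf = mk.water_fractions(BandFitResult(REGIONS["oh_stretch"], comps,
                                          (0.0, 0.0), 0.0))
    assert wf.phi_strong == pytest.approx(1.0)
    assert wf.phi_less == wf.phi_weak == 0.0


def test_wrong_component_count_rejected():
    from mesokit.ftir import BandFitResult
    comps = [mk.BandComponent("a", 3300.0, 80.0, 1.0),
             mk.BandComponent("b", 3450.0, 70.0, 1.0)]
    with pytest.raises(ValueError, match="3 components"):
        mk.water_fractions(BandFitResult(REGIONS["oh_stretch"], comps,
                                         (0.0, 0.0), 0.0))


def test_preset_fractions_recovered_within_003(ftir_fits):
    sc = mk.m70_w30(seed=6)
    for T, fit in ftir_fits["M70"]["oh_stretch"]:
        wf = mk.water_fractions(fit)
        truth = sc.ftir.phi(T, sc.kink_temperature)
        got = np.array([wf.phi_strong, wf.phi_less, wf.phi_weak])
        assert np.all(np.abs(got - truth) < 0.03), T
        assert wf.phi_strong + wf.phi_less + wf.phi_weak == pytest.approx(1.0,
                                                                          abs=1e-9)


# ---------------------------------------------------------------------------
# carbonyl ratio


def co_fit(amp_bonded, amp_free):
    from mesokit.ftir import BandFitResult
    comps = [mk.BandComponent("CO_bonded", 1725.0, 7.0, amp_bonded),
             mk.BandComponent("CO_free", 1736.0, 7.0, amp_free)]
    return BandFitResult(REGIONS["carbonyl"], comps, (0.0, 0.0), 0.0)


def test_equal_amplitudes_give_unit_ratio():
    assert mk.carbonyl_ratio(co_fit(1.0, 1.0)).amplitude_ratio == pytest.approx(1.0)


def test_ratio_is_high_over_low_frequency_amplitude():
    assert mk.carbonyl_ratio(co_fit(4.0, 2.0)).amplitude_ratio == pytest.approx(0.5)


def test_zero_bonded_amplitude_is_an_error():
    with pytest.raises(ZeroDivisionError):
        mk.carbonyl_ratio(co_fit(0.0, 1.0))


def test_ratio_directions_opposite_between_presets(ftir_fits):
    slopes = {}
    for name in ("M70", "M55"):
        T = [t for t, _ in ftir_fits[name]["carbonyl"]]
        r = [mk.carbonyl_ratio(f).amplitude_ratio
             for _, f in ftir_fits[name]["carbonyl"]]
        slopes[name] = np.polyfit(T, r, 1)[0]
    assert slopes["M70"] > 0  # free carbonyls grow without excess water
    assert slopes["M55"] < 0  # and shrink with it


# ---------------------------------------------------------------------------
# trends


def test_linear_centre_drift_has_no_discontinuity():
    from mesokit.ftir import BandFitResult
    fits = []
    for T in np.arange(28.0, 71.0, 3.0):
        comps = [mk.BandComponent("CH2_sym", 2856.0 + 0.03 * (T - 28), 10.0, 1.0)]
        region = dataclasses.replace(REGIONS["ch_stretch"],
                                     component_labels=("CH2_sym",),
                                     init_centers=(2856.0,), init_widths=(10.0,))
        fits.append((T, BandFitResult(region, comps, (0.0, 0.0), 0.0)))
    assert mk.band_center_trend(fits, "CH2_sym").discontinuity is None


def test_programmed_phi_break_found_within_one_step():
    sc = mk.m70_w30(seed=8)
    series = mk.gen_ftir_series(sc, seed=8)
    phi = []
    for k, s in enumerate(sorted(series, key=lambda s: s.temperature)):
        wf = mk.water_fractions(mk.fit_band(s, "oh_stretch", seed=8 + k))
        phi.append((s.temperature, wf.phi_strong))
    trend = mk.series_discontinuity([p[0] for p in phi], [p[1] for p in phi])
    assert trend.discontinuity is not None
    assert abs(trend.discontinuity - 55.0) <= 3.0


def test_tethered_series_fit_tightens_population_recovery(ftir_series):
    """Pinning OH centres/widths across the series must not degrade, and
    typically improves, the per-temperature population estimates."""
    sc = mk.m70_w30(seed=6)
    series = ftir_series["M70"]

    def max_err(mode):
        tf = mk.fit_band_series(series, "oh_stretch", seed=6, mode=mode)
        errs = []
        for T, fit in tf:
            truth = sc.ftir.phi(T, sc.kink_temperature)[0]
            errs.append(abs(mk.water_fractions(fit).phi_strong - truth))
        return max(errs)

    assert max_err("tethered") <= max_err("free") + 1e-3
    assert max_err("tethered") < 0.01


def test_excess_water_phi_series_stays_linear(ftir_fits):
    phi = [(T, mk.water_fractions(f).phi_strong)
           for T, f in ftir_fits["M55"]["oh_stretch"]]
    trend = mk.series_discontinuity([p[0] for p in phi], [p[1] for p in phi])
    assert trend.discontinuity is None


def test_methylene_step_detected_in_both_presets(ftir_fits):
    for name in ("M70", "M55"):
        trend = mk.band_center_trend(ftir_fits[name]["ch_stretch"], "CH_methylene")
        assert trend.discontinuity is not None, name
        assert abs(trend.discontinuity - 55.0) <= 3.0, name


def test_missing_component_label_raises_key_error(ftir_fits):
    _, fit = ftir_fits["M70"]["carbonyl"][0]
    with pytest.raises(KeyError):
        fit.component("no_such_band")
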