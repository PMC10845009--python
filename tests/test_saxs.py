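"""SAXS peak detection, ratio indexing, lattice fits and the phase diagram."""

import dataclasses
import itertools

import numpy as np
import pytest

import mesokit as mk
from mesokit.saxs import (AmbiguousPeaksError, DegenerateGeometryError, HII,
                          PN3M, PeakSet, PhaseAssignment, UnindexedError)


def lorentzian_pattern(q, centers, amps, hwhm=0.018, bg=1.0):
    y = np.full_like(q, bg)
    for c, a in zip(centers, amps):
        y = y + a * hwhm ** 2 / ((q - c) ** 2 + hwhm ** 2)
    return y


# ---------------------------------------------------------------------------
# peak detection


def test_single_gaussian_bump_found_at_its_centre():
    q = np.linspace(0.5, 1.5, 800)
    y = 1.0 + 5.0 * np.exp(-0.5 * ((q - 1.0) / 0.02) ** 2)
    pat = mk.SAXSPattern(q, y, 30.0, 30.0)
    peaks = mk.detect_peaks(pat)
    assert len(peaks) == 1
    assert peaks.positions[0] == pytest.approx(1.0, abs=q[1] - q[0])


def test_constant_intensity_yields_empty_peakset():
    q = np.linspace(0.5, 1.5, 200)
    peaks = mk.detect_peaks(mk.SAXSPattern(q, np.ones_like(q), 30.0, 30.0))
    assert len(peaks) == 0


def test_non_monotone_q_rejected():
    with pytest.raises(ValueError, match="strictly increasing"):
        mk.SAXSPattern(np.array([1.0, 0.9, 1.1]), np.ones(3), 30.0, 30.0)


def test_six_pn3m_reflections_recovered_within_half_percent():
    """1% multiplicative noise, positions against the generating q_hkl."""
    rng = np.random.default_rng(7)
    truth = PN3M.q_positions(10.0)
    q = np.linspace(0.3, 3.5, 1500)
    y = lorentzian_pattern(q, truth, [100, 80, 50, 45, 30, 25])
    y = y * (1.0 + 0.01 * rng.standard_normal(q.size))
    peaks = mk.detect_peaks(mk.SAXSPattern(q, np.maximum(y, 0), 30.0, 30.0))
    assert len(peaks) == 6
    np.testing.assert_allclose(peaks.positions, truth, rtol=0.005)


# ---------------------------------------------------------------------------
# indexing


def peakset(positions):
    positions = np.sort(np.asarray(positions, dtype=float))
    return PeakSet(positions, np.ones_like(positions))


def test_pn3m_ratio_set_indexed_with_all_six_matched():
    peaks = peakset(0.9 * PN3M.spacing_ratios)
    a = mk.index_phase(peaks)
    assert a.phases == ("Pn3m",)
    assert len(a.matched_peaks["Pn3m"]) == 6
    assert a.residual == pytest.approx(0.0, abs=1e-12)


def test_hexagonal_ratio_set_indexed_as_hii():
    peaks = peakset(1.3 * HII.spacing_ratios)
    a = mk.index_phase(peaks)
    assert a.phases == ("HII",)
    assert len(a.matched_peaks["HII"]) == 3


def test_single_peak_is_ambiguous():
    with pytest.raises(AmbiguousPeaksError):
        mk.index_phase(peakset([1.0]))


def test_unmatchable_peaks_raise_unindexed():
    with pytest.raises(UnindexedError):
        mk.index_phase(peakset([1.0, 1.09]), tolerance=0.01)


def test_coexistence_partition_matches_exhaustive_assignment():
    """Greedy two-phase decomposition against brute force over all
    peak-to-phase assignments (regression SSE as the criterion)."""
    qp = PN3M.q_positions(9.5)
    qh = HII.q_positions(5.5)
    pos = np.sort(np.concatenate([qp, qh]))
    truth = {round(q, 9): ("Pn3m" if q in qp else "HII") for q in pos}

    rules = {"Pn3m": PN3M, "HII": HII}

    def regression_sse(qs, rule, refl_idx):
        s = np.array([rule.moduli[j] for j in refl_idx])
        qs = np.asarray(qs)
        slope = qs @ s / (s @ s)
        return float(np.sum((qs - slope * s) ** 2))

    best = None
    for labels in itertools.product(["Pn3m", "HII"], repeat=pos.size):
        groups = {"Pn3m": [], "HII": []}
        for q, lbl in zip(pos, labels):
            groups[lbl].append(q)
        if any(len(v) < 2 for v in groups.values()):
            continue
        sse = 0.0
        ok = True
        for lbl, qs in groups.items():
            rule = rules[lbl]
            if len(qs) > len(rule.moduli):
                ok = False
                break
            # reflections assigned in order (positions sorted)
            ratios = np.asarray(qs) / qs[0]
            refl = []
            for r in ratios:
                j = int(np.argmin(np.abs(rule.spacing_ratios - r)))
                refl.append(j)
            if len(set(refl)) != len(refl):
                ok = False
                break
            sse += regression_sse(qs, rule, refl)
        if ok and (best is None or sse < best[0]):
            best = (sse, labels)
    oracle = dict(zip(np.round(pos, 9), best[1]))

    a = mk.index_phase(peakset(pos))
    assert set(a.phases) == {"Pn3m", "HII"}
    got = {}
    for phase, pairs in a.matched_peaks.items():
        for _, q in pairs:
            got[round(q, 9)] = phase
    assert got == oracle == truth
    assert a.lattice_parameters["Pn3m"] == pytest.approx(9.5, rel=1e-9)
    assert a.lattice_parameters["HII"] == pytest.approx(5.5, rel=1e-9)


@pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
def test_indexing_is_scale_invariant(scale):
    base = peakset(PN3M.q_positions(9.0))
    scaled = peakset(PN3M.q_positions(9.0) * scale)
    a0 = mk.index_phase(base)
    a1 = mk.index_phase(scaled)
    assert a0.phases == a1.phases
    assert a1.residual == pytest.approx(a0.residual, abs=1e-12)
    assert a1.lattice_parameters["Pn3m"] == pytest.approx(
        a0.lattice_parameters["Pn3m"] / scale, rel=1e-12)


@pytest.mark.parametrize("rule,a_true", [(PN3M, 8.7), (HII, 5.9), (mk.IA3D, 12.4)])
def test_round_trip_recovers_rule_and_lattice_exactly(rule, a_true):
    a = mk.index_phase(peakset(rule.q_positions(a_true)))
    assert a.phases == (rule.phase_label,)
    assert a.lattice_parameters[rule.phase_label] == pytest.approx(a_true, rel=1e-12)


def test_pn3m_and_hii_never_confused_at_default_tolerance():
    """Even though 1:sqrt3:sqrt4 is a ratio subset of the Pn3m list, a
    full peak set of either phase must index as itself."""
    for rule, other in ((PN3M, HII), (HII, PN3M)):
        a = mk.index_phase(peakset(rule.q_positions(7.5)), tolerance=0.015)
        assert a.phases[0] == rule.phase_label != other.phase_label


# ---------------------------------------------------------------------------
# lattice parameter


def test_noiseless_pn3m_lattice_exact():
    a = mk.index_phase(peakset(PN3M.q_positions(10.0)))
    assert a.lattice_parameters["Pn3m"] == pytest.approx(10.0, rel=1e-12)


def test_single_hexagonal_peak_closed_form():
    q10 = 4.0 * np.pi / (np.sqrt(3.0) * 6.0)
    assignment = PhaseAssignment(
        phases=("HII",), matched_peaks={"HII": [((1, 0), q10)]},
        lattice_parameters={}, residual=0.0, unmatched=())
    out = mk.fit_lattice_parameter(assignment)
    assert out.lattice_parameters["HII"] == pytest.approx(6.0, rel=1e-12)


def test_degenerate_zero_positions_rejected():
    assignment = PhaseAssignment(
        phases=("HII",), matched_peaks={"HII": [((1, 0), 0.0)]},
        lattice_parameters={}, residual=0.0, unmatched=())
    with pytest.raises(DegenerateGeometryError):
        mk.fit_lattice_parameter(assignment)


def test_jittered_lattice_matches_direct_regression():
    """0.5% multiplicative jitter; oracle = least squares on the table."""
    rng = np.random.default_rng(3)
    qs = PN3M.q_positions(10.0) * (1.0 + 0.005 * rng.standard_normal(6))
    qs = np.sort(qs)
    a = mk.index_phase(peakset(qs))
    mod = dict(zip(PN3M.miller_indices, PN3M.moduli))
    pairs = a.matched_peaks["Pn3m"]
    s = np.array([mod[hkl] for hkl, _ in pairs])
    qm = np.array([q for _, q in pairs])
    slope = qm @ s / (s @ s)
    assert a.lattice_parameters["Pn3m"] == pytest.approx(2 * np.pi / slope, rel=1e-9)
    assert abs(a.lattice_parameters["Pn3m"] - 10.0) / 10.0 < 0.005


# ---------------------------------------------------------------------------
# excess-water boundary


def test_noiseless_plateau_boundary_at_40_wt():
    wt = np.arange(25.0, 51.0, 2.5)
    a = np.where(wt <= 40.0, 9.3 + 0.09 * (wt - 25.0), 9.3 + 0.09 * 15.0)
    assert mk.detect_excess_water_boundary(list(zip(wt, a))) == pytest.approx(40.0)


def test_strictly_increasing_series_has_no_boundary():
    wt = np.arange(25.0, 51.0, 2.5)
    a = 9.3 + 0.09 * (wt - 25.0)
    assert mk.detect_excess_water_boundary(list(zip(wt, a))) is None


def test_unsorted_series_rejected():
    with pytest.raises(ValueError, match="sorted"):
        mk.detect_excess_water_boundary([(30.0, 9.5), (25.0, 9.3),
                                         (35.0, 9.8), (40.0, 10.0)])


def test_noisy_boundary_within_one_step_of_brute_force_scan(m70):
    series = mk.gen_lattice_vs_water(m70, seed=11)
    wt = np.array([p[0] for p in series])
    a = np.array([p[1] for p in series])

    def sse_at(i):
        A = np.column_stack([np.ones_like(wt), np.minimum(wt - wt[i], 0.0)])
        c, *_ = np.linalg.lstsq(A, a, rcond=None)
        return float(np.sum((a - A @ c) ** 2))

    oracle = wt[min(range(1, wt.size - 1), key=sse_at)]
    found = mk.detect_excess_water_boundary(series)
    assert found is not None
    assert abs(found - oracle) <= 2.5
    assert abs(found - 40.0) <= 2.5


# ---------------------------------------------------------------------------
# phase diagram


def test_preset_grid_reproduces_the_three_phase_bands(saxs70):
    diagram = mk.build_phase_diagram(saxs70)
    by_T = {e["temperature"]: e["assignment"] for e in diagram.grid}
    for T, want in [(30.0, ("Pn3m",)), (46.0, ("Pn3m",)),
                    (50.0, ("Pn3m", "HII")), (62.0, ("Pn3m", "HII")),
                    (66.0, ("HII",))]:
        assert set(by_T[T].phases) == set(want), T
    assert diagram.coexistence_window() == (50.0, 62.0)


def test_single_phase_grid_is_uniform_without_coexistence(m70):
    hot = dataclasses.replace(m70, saxs_temperatures=(66.0, 70.0))
    diagram = mk.build_phase_diagram(mk.gen_saxs_series(hot, seed=1))
    assert all(e["assignment"].phases == ("HII",) for e in diagram.grid)
    assert diagram.coexistence_window() is None


def test_composition_grid_boundary_monotone_and_flag_is_step_function(m70):
    pats = []
    for wt in np.arange(27.5, 47.6, 2.5):
        sc = dataclasses.replace(m70, water_wt=float(wt),
                                 saxs_temperatures=(30.0, 38.0, 46.0))
        pats += mk.gen_saxs_series(sc, seed=3)
    diagram = mk.build_phase_diagram(pats)
    bounds = [diagram.excess_boundary[T] for T in sorted(diagram.excess_boundary)]
    assert all(b is not None for b in bounds)
    assert all(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:]))  # non-increasing
    df = diagram.to_frame()
    for T, grp in df.groupby("temperature"):
        flags = grp.sort_values("water_wt")["excess_water"].to_numpy()
        assert np.all(np.diff(flags.astype(int)) >= 0)  # one False->True switch


def test_unindexable_state_point_reported_not_fatal(m70):
    pats = mk.gen_saxs_series(
        dataclasses.replace(m70, saxs_temperatures=(30.0, 34.0)), seed=1)
    q = np.linspace(0.3, 3.5, 500)
    flat = mk.SAXSPattern(q, np.ones_like(q), 38.0, 30.0)
    diagram = mk.build_phase_diagram(pats + [flat])
    entry = [e for e in diagram.grid if e["temperature"] == 38.0][0]
    assert entry["assignment"] is None
    assert all(e["assignment"] is not None for e in diagram.grid
               if e["temperature"] != 38.0)
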