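"""Synthetic SAXS / BDS / FTIR series from declarative ground-truth scenarios.

A :class:`Scenario` holds explicit per-temperature schedules — which
phase is present, how the lattice parameter evolves with temperature and
hydration (including the excess-water plateau), per-process Arrhenius
branches for the dielectric relaxation times with a slope change at the
phase transition, and per-band centre/area schedules for the infrared
components.  The generators evaluate those schedules on the experimental
temperature grids and add seeded noise, producing data with the
statistical structure the analysis modules assume.  Analysis code never
reads a Scenario: generators talk to the analysis only through the
generated arrays, so recovery tests are honest.

Two presets emulate the studied compositions: ``m70_w30`` (70:30
lipid:water, no excess water — slow dynamics, OH-population and
band-centre discontinuities at the transition) and ``m55_w45`` (45 wt%
water, excess water present — every relaxation process faster, linear
OH populations, opposite carbonyl-ratio trend).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .dielectric import DielectricModel, DielectricSpectrum, HNProcess, evaluate_model
from .ftir import BandComponent, FTIRSpectrum
from .saxs import HII, PN3M, SAXSPattern

__all__ = [
    "Scenario", "SAXSSchedule", "ProcessSchedule", "BDSSchedule",
    "ComponentSchedule", "FTIRSchedule", "m70_w30", "m55_w45",
    "gen_saxs_series", "gen_bds_series", "gen_ftir_series",
    "gen_lattice_vs_water",
]

# distinct child-seed tags per modality so one scenario seed yields
# independent but reproducible streams
_SAXS_TAG, _BDS_TAG, _FTIR_TAG, _LATTICE_TAG = 101, 202, 303, 404


def _interp_arrhenius(anchors: tuple[tuple[float, float], ...], T: float) -> float:
    """Piecewise-linear interpolation in inverse absolute temperature."""
    xs = np.array([1.0 / (t + 273.15) for t, _ in anchors])
    ys = np.array([v for _, v in anchors])
    order = np.argsort(xs)
    return float(np.interp(1.0 / (T + 273.15), xs[order], ys[order]))


@dataclass(frozen=True)
class SAXSSchedule:
    """Lattice-parameter and peak-shape schedule."""

    a_ref: float = 9.3            # Pn3m lattice parameter, nm, at (wt_ref, 30 C)
    wt_ref: float = 25.0          # reference hydration, wt%
    swell_rate: float = 0.09      # nm per wt% below the plateau
    plateau_wt_30C: float = 40.0  # excess-water boundary at 30 C, wt%
    plateau_dwdT: float = -0.1    # boundary drift, wt% per degC (non-increasing)
    pn3m_dadT: float = -0.02      # nm per degC
    hii_a0: float = 5.6           # H_II lattice parameter at 30 C, nm
    hii_dadT: float = -0.01
    crossfade_pad: float = 2.0    # degC of crossfade beyond the window edges
    q_min: float = 0.3            # nm^-1
    q_max: float = 3.5
    n_q: int = 1500
    peak_hwhm: float = 0.018      # Lorentzian half width, nm^-1
    pn3m_amps: tuple[float, ...] = (1.0, 0.8, 0.5, 0.45, 0.3, 0.25)
    hii_amps: tuple[float, ...] = (1.0, 0.5, 0.35)
    pn3m_scale: float = 100.0
    hii_scale: float = 120.0
    bg_amp: float = 5.0           # power-law background amplitude
    bg_exp: float = -2.0
    bg_const: float = 1.0


@dataclass(frozen=True)
class ProcessSchedule:
    """One relaxation process: Arrhenius branches + HN shape."""

    log_tau_anchors: tuple[tuple[float, float], ...]  # (T degC, log10 tau_HN s)
    delta_eps: float
    alpha: float
    gamma: float

    def tau_hn(self, T: float) -> float:
        return 10.0 ** _interp_arrhenius(self.log_tau_anchors, T)


@dataclass(frozen=True)
class BDSSchedule:
    processes: tuple[ProcessSchedule, ...]
    eps_inf: float = 3.0
    log_sigma_anchors: tuple[tuple[float, float], ...] = ((31.0, -11.3), (70.0, -10.6))
    f_min: float = 1e-2           # Hz
    f_max: float = 1e6
    points_per_decade: int = 10

    def sigma(self, T: float) -> float:
        return 10.0 ** _interp_arrhenius(self.log_sigma_anchors, T)


@dataclass(frozen=True)
class ComponentSchedule:
    """Centre/width/amplitude schedule of one infrared sub-band.

    ``center_step`` and the amplitude schedule apply a jump for
    temperatures above the scenario kink (discontinuity at the phase
    transition); slopes are per degC relative to ``t_ref``.
    """

    label: str
    center0: float
    center_slope: float = 0.0
    center_step: float = 0.0
    width: float = 10.0
    amp0: float = 0.5
    amp_slope: float = 0.0

    def center(self, T: float, t_ref: float, kink: float) -> float:
        c = self.center0 + self.center_slope * (T - t_ref)
        if T > kink:
            c += self.center_step
        return c

    def amplitude(self, T: float, t_ref: float) -> float:
        return max(self.amp0 + self.amp_slope * (T - t_ref), 0.0)


@dataclass(frozen=True)
class FTIRSchedule:
    components: tuple[ComponentSchedule, ...]   # non-OH bands
    oh: tuple[ComponentSchedule, ...]           # 3 OH bands; amplitudes from phi
    phi0: tuple[float, float, float]
    phi_slope: tuple[float, float, float]       # per degC; must sum to 0
    phi_step: tuple[float, float, float]        # jump above the kink; sums to 0
    a_tot: float = 60.0                          # total OH band area, a.u. cm^-1
    t_ref: float = 28.0
    baseline: tuple[float, float] = (0.02, 1.0e-5)
    wn_min: float = 1000.0
    wn_max: float = 3800.0
    wn_step: float = 2.0                         # spectrometer resolution, cm^-1

    def phi(self, T: float, kink: float) -> np.ndarray:
        phi = np.array(self.phi0) + np.array(self.phi_slope) * (T - self.t_ref)
        if T > kink:
            phi = phi + np.array(self.phi_step)
        phi = np.clip(phi, 0.0, None)
        return phi / phi.sum()


@dataclass(frozen=True)
class Scenario:
    """Declarative ground truth for one sample composition."""

    name: str
    water_wt: float
    transition_window: tuple[float, float] = (50.0, 62.0)
    kink_temperature: float = 55.0
    saxs_temperatures: tuple[float, ...] = tuple(range(30, 67, 4))
    bds_temperatures: tuple[float, ...] = tuple(range(31, 71, 3))
    ftir_temperatures: tuple[float, ...] = tuple(range(28, 71, 3))
    saxs: SAXSSchedule = field(default_factory=SAXSSchedule)
    bds: BDSSchedule = field(default_factory=lambda: BDSSchedule(processes=()))
    ftir: FTIRSchedule = field(default_factory=lambda: FTIRSchedule(
        components=(), oh=(), phi0=(1 / 3, 1 / 3, 1 / 3),
        phi_slope=(0.0, 0.0, 0.0), phi_step=(0.0, 0.0, 0.0)))
    saxs_noise: float = 0.01
    bds_noise: float = 0.005
    ftir_noise: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.transition_window
        if not lo < self.kink_temperature < hi:
            raise ValueError("kink must lie inside the transition window")
        for arr in (self.ftir.phi_slope, self.ftir.phi_step):
            if abs(sum(arr)) > 1e-12:
                raise ValueError("phi slopes/steps must sum to zero")

    # -- SAXS ground truth --------------------------------------------------

    def plateau_wt(self, T: float) -> float:
        s = self.saxs
        return s.plateau_wt_30C + s.plateau_dwdT * (T - 30.0)

    def pn3m_a(self, T: float, water_wt: float | None = None) -> float:
        s = self.saxs
        wt = self.water_wt if water_wt is None else water_wt
        wt_eff = min(wt, self.plateau_wt(T))
        return s.a_ref + s.swell_rate * (wt_eff - s.wt_ref) + s.pn3m_dadT * (T - 30.0)

    def hii_a(self, T: float) -> float:
        return self.saxs.hii_a0 + self.saxs.hii_dadT * (T - 30.0)

    def crossfade(self, T: float) -> float:
        """H_II amplitude weight: 0 pure Pn3m, 1 pure H_II."""
        lo, hi = self.transition_window
        pad = self.saxs.crossfade_pad
        return float(np.clip((T - (lo - pad)) / ((hi + pad) - (lo - pad)), 0.0, 1.0))

    def phase_at(self, T: float) -> str:
        x = self.crossfade(T)
        if x <= 0.0:
            return "Pn3m"
        if x >= 1.0:
            return "HII"
        return "coexistence"

    def saxs_truth(self, T: float) -> dict:
        """Scheduled phases, lattice parameters and Bragg positions at T."""
        x = self.crossfade(T)
        out = {"phase": self.phase_at(T), "weight_hii": x, "peaks": {}}
        if x < 1.0:
            a = self.pn3m_a(T)
            out["peaks"]["Pn3m"] = PN3M.q_positions(a)
            out["a_Pn3m"] = a
        if x > 0.0:
            a = self.hii_a(T)
            out["peaks"]["HII"] = HII.q_positions(a)
            out["a_HII"] = a
        return out

    # -- BDS ground truth ---------------------------------------------------

    def bds_model(self, T: float) -> DielectricModel:
        procs = tuple(
            HNProcess(p.delta_eps, p.tau_hn(T), p.alpha, p.gamma)
            for p in self.bds.processes)
        return DielectricModel(procs, eps_inf=self.bds.eps_inf,
                               sigma=self.bds.sigma(T))

    # -- FTIR ground truth --------------------------------------------------

    def ftir_components(self, T: float) -> list[BandComponent]:
        f = self.ftir
        comps = [
            BandComponent(c.label,
                          c.center(T, f.t_ref, self.kink_temperature),
                          c.width, c.amplitude(T, f.t_ref))
            for c in f.components]
        phi = f.phi(T, self.kink_temperature)
        for c, p in zip(f.oh, phi):
            amp = p * f.a_tot / (c.width * math.sqrt(2.0 * math.pi))
            comps.append(BandComponent(
                c.label, c.center(T, f.t_ref, self.kink_temperature),
                c.width, amp))
        return comps

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# presets


def m70_w30(seed: int = 0) -> Scenario:
    """70:30 lipid:water — no excess water.

    Slowest process spans 0.1–100 s; all OH populations, the methylene
    CH centre and the headgroup bands jump at the transition; the
    free:H-bonded carbonyl ratio rises on heating.
    """
    bds = BDSSchedule(processes=(
        ProcessSchedule(((31.0, 2.0), (55.0, -0.3), (70.0, -1.0)),
                        delta_eps=60.0, alpha=0.95, gamma=1.0),
        ProcessSchedule(((31.0, -2.5), (55.0, -3.5), (70.0, -3.3)),
                        delta_eps=8.0, alpha=0.85, gamma=0.9),
        ProcessSchedule(((31.0, -5.0), (55.0, -5.8), (70.0, -6.0)),
                        delta_eps=3.0, alpha=0.8, gamma=1.0),
    ))
    ftir = FTIRSchedule(
        components=(
            ComponentSchedule("Sn3", 1050.0, -0.02, -1.0, 15.0, 0.30),
            ComponentSchedule("Sn2", 1120.0, -0.02, -1.0, 15.0, 0.35),
            ComponentSchedule("Sn1", 1180.0, -0.03, -1.0, 12.0, 0.50),
            ComponentSchedule("CO_bonded", 1725.0, -0.03, 0.0, 7.0, 0.50, -0.002),
            ComponentSchedule("CO_free", 1736.0, -0.03, 0.0, 7.0, 0.40, +0.003),
            ComponentSchedule("CH2_sym", 2856.0, 1.0 / 36.0, 0.0, 10.0, 0.90),
            ComponentSchedule("CH2_asym", 2924.0, 1.0 / 36.0, 0.0, 12.0, 1.00),
            ComponentSchedule("CH_methylene", 3010.0, 0.0, -2.0, 10.0, 0.35),
        ),
        oh=(
            ComponentSchedule("OH_strong", 3300.0, width=80.0),
            ComponentSchedule("OH_less", 3450.0, width=70.0),
            ComponentSchedule("OH_weak", 3600.0, width=50.0),
        ),
        phi0=(0.45, 0.35, 0.20),
        phi_slope=(-0.0020, 0.0013, 0.0007),
        phi_step=(-0.040, 0.025, 0.015),
        a_tot=60.0,
    )
    return Scenario(name="M70-W30", water_wt=30.0, bds=bds, ftir=ftir, seed=seed)


def m55_w45(seed: int = 0) -> Scenario:
    """55:45 lipid:water — mesophase in equilibrium with excess water.

    Every relaxation process is faster than in M70-W30 at every common
    temperature (plasticizer effect; slowest process 0.001–0.1 s); OH
    populations evolve linearly (bulk-like excess water dominates); the
    carbonyl ratio falls on heating and both CO sub-bands blue-shift.
    """
    bds = BDSSchedule(processes=(
        ProcessSchedule(((31.0, -1.0), (55.0, -2.5), (70.0, -3.0)),
                        delta_eps=60.0, alpha=0.95, gamma=1.0),
        ProcessSchedule(((31.0, -3.5), (55.0, -4.5), (70.0, -4.3)),
                        delta_eps=8.0, alpha=0.85, gamma=0.9),
        ProcessSchedule(((31.0, -5.8), (55.0, -6.3), (70.0, -6.6)),
                        delta_eps=3.0, alpha=0.8, gamma=1.0),
    ))
    ftir = FTIRSchedule(
        components=(
            ComponentSchedule("Sn3", 1050.0, -0.015, -0.8, 15.0, 0.30),
            ComponentSchedule("Sn2", 1120.0, -0.015, -0.8, 15.0, 0.35),
            ComponentSchedule("Sn1", 1180.0, -0.02, -0.8, 12.0, 0.50),
            ComponentSchedule("CO_bonded", 1725.0, +0.03, 0.0, 7.0, 0.45, +0.002),
            ComponentSchedule("CO_free", 1736.0, +0.03, 0.0, 7.0, 0.54, -0.002),
            ComponentSchedule("CH2_sym", 2856.0, 0.6 / 42.0, 0.0, 10.0, 0.90),
            ComponentSchedule("CH2_asym", 2924.0, 0.6 / 42.0, 0.0, 12.0, 1.00),
            ComponentSchedule("CH_methylene", 3010.0, 0.0, -0.8, 10.0, 0.35),
        ),
        oh=(
            ComponentSchedule("OH_strong", 3300.0, width=80.0),
            ComponentSchedule("OH_less", 3450.0, width=70.0),
            ComponentSchedule("OH_weak", 3600.0, width=50.0),
        ),
        phi0=(0.50, 0.33, 0.17),
        phi_slope=(-0.0025, 0.0017, 0.0008),
        phi_step=(0.0, 0.0, 0.0),
        a_tot=90.0,
    )
    return Scenario(name="M55-W45", water_wt=45.0, bds=bds, ftir=ftir, seed=seed)


# ---------------------------------------------------------------------------
# generators


def _rng(scenario: Scenario, tag: int, seed: int | None) -> np.random.Generator:
    base = scenario.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base) % 2**31, tag]))


def gen_saxs_series(scenario: Scenario, seed: int | None = None) -> list[SAXSPattern]:
    """Lorentzian Bragg peaks of the scheduled phase(s) on a power-law
    background, coexistence as a linear amplitude crossfade, multiplicative
    noise.  Deterministic under a fixed seed."""
    rng = _rng(scenario, _SAXS_TAG, seed)
    s = scenario.saxs
    q = np.linspace(s.q_min, s.q_max, s.n_q)
    out = []
    for T in scenario.saxs_temperatures:
        x = scenario.crossfade(T)
        y = s.bg_amp * q ** s.bg_exp + s.bg_const
        truth = scenario.saxs_truth(T)
        if "Pn3m" in truth["peaks"]:
            for q0, amp in zip(truth["peaks"]["Pn3m"], s.pn3m_amps):
                y = y + (1.0 - x) * s.pn3m_scale * amp * s.peak_hwhm ** 2 / (
                    (q - q0) ** 2 + s.peak_hwhm ** 2)
        if "HII" in truth["peaks"]:
            for q0, amp in zip(truth["peaks"]["HII"], s.hii_amps):
                y = y + x * s.hii_scale * amp * s.peak_hwhm ** 2 / (
                    (q - q0) ** 2 + s.peak_hwhm ** 2)
        y = y * (1.0 + scenario.saxs_noise * rng.standard_normal(q.size))
        out.append(SAXSPattern(q, np.maximum(y, 0.0), float(T), scenario.water_wt))
    return out


def gen_bds_series(scenario: Scenario, seed: int | None = None) -> list[DielectricSpectrum]:
    """Scheduled HN models evaluated on the log-frequency measurement grid
    with relative noise on both permittivity components."""
    rng = _rng(scenario, _BDS_TAG, seed)
    b = scenario.bds
    decades = math.log10(b.f_max / b.f_min)
    n = int(round(decades * b.points_per_decade)) + 1
    f = np.logspace(math.log10(b.f_min), math.log10(b.f_max), n)
    out = []
    for T in scenario.bds_temperatures:
        clean = evaluate_model(scenario.bds_model(T), f,
                               temperature=float(T), water_wt=scenario.water_wt)
        er = clean.eps_real * (1.0 + scenario.bds_noise * rng.standard_normal(n))
        ei = clean.eps_imag * (1.0 + scenario.bds_noise * rng.standard_normal(n))
        out.append(DielectricSpectrum(f, er, np.maximum(ei, 0.0),
                                      float(T), scenario.water_wt))
    return out


def gen_ftir_series(scenario: Scenario, seed: int | None = None) -> list[FTIRSpectrum]:
    """Sum of scheduled Gaussian bands on a linear baseline with
    multiplicative noise, over the full 1000-3800 cm^-1 range."""
    rng = _rng(scenario, _FTIR_TAG, seed)
    fsch = scenario.ftir
    wn = np.arange(fsch.wn_min, fsch.wn_max + 0.5 * fsch.wn_step, fsch.wn_step)
    out = []
    for T in scenario.ftir_temperatures:
        y = fsch.baseline[0] + fsch.baseline[1] * (wn - fsch.wn_min)
        for c in scenario.ftir_components(T):
            y = y + c(wn)
        y = y * (1.0 + scenario.ftir_noise * rng.standard_normal(wn.size))
        out.append(FTIRSpectrum(wn, np.maximum(y, 0.0), float(T), scenario.water_wt))
    return out


def gen_lattice_vs_water(
    scenario: Scenario, temperature: float = 30.0,
    compositions: np.ndarray | None = None,
    noise: float = 0.003, seed: int | None = None,
) -> list[tuple[float, float]]:
    """Lattice parameter versus hydration at fixed temperature, with
    relative noise — the input of the excess-water boundary detector."""
    rng = _rng(scenario, _LATTICE_TAG, seed)
    if compositions is None:
        compositions = np.arange(25.0, 50.0 + 1e-9, 2.5)
    out = []
    for wt in compositions:
        a = scenario.pn3m_a(temperature, water_wt=float(wt))
        a *= 1.0 + noise * rng.standard_normal()
        out.append((float(wt), float(a)))
    return out
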