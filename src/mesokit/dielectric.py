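"""Broadband dielectric spectroscopy: Havriliak-Negami relaxation analysis.

The complex permittivity of a lipid mesophase is modelled as a sum of
Havriliak-Negami (HN) processes plus a dc-conductivity term,

    eps*(w) = eps_inf + sum_k  d_eps_k / (1 + (i w tau_HN_k)**alpha_k)**gamma_k,
    eps''_total(w) = -Im eps*(w) + sigma / (w eps_0),

with 0 < alpha_k <= 1 and 0 < alpha_k*gamma_k <= 1 describing symmetric
and asymmetric broadening (alpha = gamma = 1 is the Debye case).  The
relaxation time at maximum loss follows from the closed form

    tau_max = tau_HN * [ sin(pi a g / (2+2g)) / sin(pi a / (2+2g)) ]**(1/a).

Spectra are fitted either on the dielectric loss eps'' or on the loss
tangent tan(delta) = eps''/eps'; for a single Debye process the tan(delta)
peak sits above the eps'' peak by the factor (1 + d_eps/eps_h)**0.5.

``DielectricSpectrumModel`` wraps one spectrum and produces a
``DielectricFitResult`` via :meth:`~DielectricSpectrumModel.fit`;
temperature series are handled by :func:`build_relaxation_map`, which
propagates each converged fit as the initialisation of the next
temperature (continuation), and :func:`detect_kink`, which tests the
Arrhenius map of a process for the slope change that accompanies the
cubic-to-hexagonal phase transition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import epsilon_0 as EPS0
from scipy.optimize import least_squares

from ._breakpoint import detect_breakpoint

__all__ = [
    "HNProcess", "DielectricModel", "DielectricSpectrum",
    "DielectricSpectrumModel", "DielectricFitResult", "RelaxationMap",
    "FitFailedError", "evaluate_model", "tan_delta", "debye_tan_delta_peak",
    "tau_max_from_hn", "fit_spectrum", "build_relaxation_map", "detect_kink",
]


class FitFailedError(RuntimeError):
    """All multistart attempts failed to converge; best attempt attached."""

    def __init__(self, message: str, best: "DielectricFitResult | None" = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class HNProcess:
    """One Havriliak-Negami relaxation process."""

    delta_eps: float   # relaxation strength, dimensionless
    tau_hn: float      # characteristic time, s
    alpha: float       # symmetric broadening, (0, 1]
    gamma: float       # asymmetric broadening, 0 < alpha*gamma <= 1

    def __post_init__(self) -> None:
        if self.delta_eps <= 0:
            raise ValueError("delta_eps must be positive")
        if self.tau_hn <= 0:
            raise ValueError("tau_hn must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.alpha * self.gamma <= 1:
            raise ValueError("alpha*gamma must lie in (0, 1]")

    @property
    def tau_max(self) -> float:
        return tau_max_from_hn(self)


@dataclass(frozen=True)
class DielectricModel:
    """Sum of HN processes + dc conductivity + high-frequency permittivity."""

    processes: tuple[HNProcess, ...]
    eps_inf: float = 2.0
    sigma: float = 0.0   # dc conductivity, S/m

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        taus = [p.tau_hn for p in self.processes]
        if taus != sorted(taus, reverse=True):
            object.__setattr__(
                self, "processes",
                tuple(sorted(self.processes, key=lambda p: -p.tau_hn)))

    def eps_complex(self, frequency: np.ndarray) -> np.ndarray:
        """eps' - i*eps'' on a frequency grid (Hz); conductivity included in eps''."""
        f = np.asarray(frequency, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        w = 2.0 * np.pi * f
        eps = np.full(f.shape, complex(self.eps_inf))
        for p in self.processes:
            eps = eps + p.delta_eps / (1.0 + (1j * w * p.tau_hn) ** p.alpha) ** p.gamma
        if self.sigma > 0:
            eps = eps - 1j * self.sigma / (w * EPS0)
        return eps


@dataclass(frozen=True)
class DielectricSpectrum:
    """Measured (or simulated) permittivity spectrum at one temperature."""

    frequency: np.ndarray   # Hz, strictly increasing
    eps_real: np.ndarray
    eps_imag: np.ndarray
    temperature: float      # degC
    water_wt: float = np.nan

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        ei = np.asarray(self.eps_imag, dtype=float)
        for name, arr in (("frequency", f), ("eps_real", er), ("eps_imag", ei)):
            object.__setattr__(self, name, arr)
        if not (f.shape == er.shape == ei.shape):
            raise ValueError("grids must have equal length")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(ei < 0):
            raise ValueError("eps_imag must be nonnegative")
        if np.any(er < 1):
            warnings.warn("eps_real < 1 encountered; check the data", stacklevel=2)

    @property
    def decades(self) -> float:
        return float(np.log10(self.frequency[-1] / self.frequency[0]))


# ---------------------------------------------------------------------------
# closed forms


def evaluate_model(model: DielectricModel, frequency: np.ndarray,
                   temperature: float = np.nan,
                   water_wt: float = np.nan) -> DielectricSpectrum:
    """Evaluate a dielectric model on a frequency grid (principal branch)."""
    eps = model.eps_complex(frequency)
    return DielectricSpectrum(
        frequency=np.asarray(frequency, dtype=float),
        eps_real=eps.real, eps_imag=-eps.imag,
        temperature=temperature, water_wt=water_wt)


def tan_delta(spectrum: DielectricSpectrum) -> np.ndarray:
    """Loss tangent eps''/eps', pointwise."""
    er = spectrum.eps_real
    if np.any(er == 0):
        f_bad = spectrum.frequency[er == 0][0]
        raise ZeroDivisionError(f"eps_real vanishes at f = {f_bad:g} Hz")
    return spectrum.eps_imag / er


def debye_tan_delta_peak(delta_eps: float, eps_h: float) -> float:
    """Position (in units of omega*tau) of the tan(delta) maximum of a
    Debye process with strength ``delta_eps`` over a high-frequency
    permittivity ``eps_h``: (1 + delta_eps/eps_h)**0.5."""
    if eps_h <= 0:
        raise ValueError("eps_h must be positive")
    if delta_eps < 0:
        raise ValueError("delta_eps must be nonnegative")
    return math.sqrt(1.0 + delta_eps / eps_h)


def tau_max_from_hn(process: HNProcess) -> float:
    """Relaxation time at the eps'' maximum from the HN shape parameters."""
    a, g = process.alpha, process.gamma
    num = math.sin(math.pi * a * g / (2.0 * (1.0 + g)))
    den = math.sin(math.pi * a / (2.0 * (1.0 + g)))
    return process.tau_hn * (num / den) ** (1.0 / a)


# ---------------------------------------------------------------------------
# fitting


_DEFAULT_BOUNDS = {
    "eps_inf": (1.0, 50.0),
    "log10_sigma": (-16.0, -6.0),
    "log10_delta_eps": (-2.0, 4.0),
    "log10_tau": (-9.0, 5.0),
    "alpha": (0.3, 1.0),
    "gamma": (0.3, 1.0),
}


def _pack(model: DielectricModel) -> np.ndarray:
    theta = [model.eps_inf, np.log10(max(model.sigma, 1e-16))]
    for p in model.processes:
        theta += [np.log10(p.delta_eps), np.log10(p.tau_hn), p.alpha, p.gamma]
    return np.asarray(theta)


def _unpack(theta: np.ndarray, n_processes: int) -> DielectricModel:
    eps_inf, log_sigma = theta[0], theta[1]
    procs = []
    for k in range(n_processes):
        lde, lt, a, g = theta[2 + 4 * k: 6 + 4 * k]
        a = min(float(a), 1.0)
        g = min(float(g), 1.0 / a)
        procs.append(HNProcess(10.0 ** lde, 10.0 ** lt, a, g))
    sigma = 10.0 ** log_sigma
    if sigma < 10 ** (_DEFAULT_BOUNDS["log10_sigma"][0] + 0.01):
        sigma = 0.0  # pinned at the lower bound: effectively no conductivity
    return DielectricModel(tuple(procs), eps_inf=float(eps_inf), sigma=sigma)


class DielectricFitResult:
    """Fitted dielectric model with uncertainties and diagnostics.

    Attributes
    ----------
    model : DielectricModel
        Converged model, processes ordered slowest first.
    params : pandas.Series
        Natural-scale parameter estimates.
    bse : pandas.Series
        Approximate standard errors (delta method from the Jacobian).
    tau_max : list of float
        Loss-peak relaxation time per process, slowest first.
    resid_rms : float
        rms of the relative residuals in the fitted representation.
    """

    def __init__(self, model, representation, theta, cov, resid_rms,
                 n_starts_used, converged, warnings_=()):
        self.model = model
        self.representation = representation
        self._theta = theta
        self._cov = cov
        self.resid_rms = float(resid_rms)
        self.n_starts_used = n_starts_used
        self.converged = bool(converged)
        self.warnings = tuple(warnings_)
        names = ["eps_inf", "sigma"]
        values = [model.eps_inf, model.sigma]
        for k, p in enumerate(model.processes, start=1):
            names += [f"delta_eps_{k}", f"tau_hn_{k}", f"alpha_{k}", f"gamma_{k}"]
            values += [p.delta_eps, p.tau_hn, p.alpha, p.gamma]
        self.params = pd.Series(values, index=names)
        self.bse = pd.Series(self._stderr(), index=names)
        self.tau_max = [p.tau_max for p in model.processes]

    def _stderr(self):
        if self._cov is None:
            return np.full(2 + 4 * len(self.model.processes), np.nan)
        se_theta = np.sqrt(np.maximum(np.diag(self._cov), 0.0))
        ln10 = math.log(10.0)
        out = [se_theta[0], ln10 * self.model.sigma * se_theta[1]]
        for k, p in enumerate(self.model.processes):
            s = se_theta[2 + 4 * k: 6 + 4 * k]
            out += [ln10 * p.delta_eps * s[0], ln10 * p.tau_hn * s[1], s[2], s[3]]
        return np.asarray(out)

    def summary(self) -> str:
        rep = {"tan_delta": "tan(delta)", "eps_imag": "eps''"}[self.representation]
        lines = [
            "Havriliak-Negami spectrum fit",
            "=" * 46,
            f"representation: {rep}   processes: {len(self.model.processes)}",
            f"rms relative residual: {self.resid_rms:.3e}"
            + ("" if self.converged else "   [NOT CONVERGED]"),
            "-" * 46,
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<14}{self.params[name]:>14.4g}{self.bse[name]:>14.2g}")
        for k, tm in enumerate(self.tau_max, start=1):
            lines.append(f"{'tau_max_' + str(k):<14}{tm:>14.4g}{'':>14}")
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


class DielectricSpectrumModel:
    """Havriliak-Negami model of one dielectric spectrum.

    Parameters
    ----------
    spectrum : DielectricSpectrum
        Must span at least three frequency decades.
    n_processes : int
        Number of HN processes, 0..4 (0 fits conductivity + eps_inf only).
    representation : {"tan_delta", "eps_imag"}
        Quantity the least squares is run on.  tan(delta) is the default.
    fit_sigma : bool
        Include the dc-conductivity term.
    bounds : dict, optional
        Overrides for the default box bounds, keyed like
        ``_DEFAULT_BOUNDS`` (gamma may be pinned by setting its bounds to
        (1.0, 1.0), for instance).
    """

    def __init__(self, spectrum: DielectricSpectrum, n_processes: int = 3,
                 representation: str = "tan_delta", fit_sigma: bool = True,
                 bounds: dict | None = None):
        if spectrum.decades < 3:
            raise ValueError("spectrum must span at least 3 frequency decades")
        if not 0 <= n_processes <= 4:
            raise ValueError("n_processes must lie in 0..4")
        if representation not in ("tan_delta", "eps_imag"):
            raise ValueError("representation must be 'tan_delta' or 'eps_imag'")
        self.spectrum = spectrum
        self.n_processes = n_processes
        self.representation = representation
        self.fit_sigma = fit_sigma
        self.bounds = dict(_DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        self._target = (tan_delta(spectrum) if representation == "tan_delta"
                        else spectrum.eps_imag)

    # -- internals ---------------------------------------------------------

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        model = _unpack(theta, self.n_processes)
        eps = model.eps_complex(self.spectrum.frequency)
        if self.representation == "tan_delta":
            return -eps.imag / eps.real
        return -eps.imag

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        pred = self._predict(theta)
        floor = 1e-6 * float(np.max(np.abs(self._target)))
        res = (pred - self._target) / (np.abs(self._target) + floor)
        if self.representation == "tan_delta":
            # tan(delta) alone fixes the model only up to a common scale
            # of (delta_eps, eps_inf, sigma); anchor the scale with the
            # measured high-frequency eps'
            model = _unpack(theta, self.n_processes)
            pred_hi = model.eps_complex(self.spectrum.frequency[-3:]).real
            data_hi = self.spectrum.eps_real[-3:]
            res = np.concatenate([res, (pred_hi - data_hi) / data_hi])
        return res

    #: tether scales per temperature step for continuation fitting:
    #: (log10 delta_eps, alpha, gamma).  A process whose loss peak has
    #: left the frequency window is degenerate on its own flank — its
    #: strength and shape are then pinned by the neighbouring
    #: temperature, while tau stays free so the Arrhenius trend is
    #: measured, not assumed.
    _TETHER_SCALES = (0.05, 0.02, 0.02)

    def _tethered_residuals(self, theta: np.ndarray, theta0: np.ndarray) -> np.ndarray:
        data = self._residuals(theta)
        pens = []
        for k in range(self.n_processes):
            base = 2 + 4 * k
            for off, scale in zip((0, 2, 3), self._TETHER_SCALES):
                pens.append((theta[base + off] - theta0[base + off]) / scale)
        return np.concatenate([data, np.asarray(pens)])

    def _theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.bounds
        lo = [b["eps_inf"][0], b["log10_sigma"][0]]
        hi = [b["eps_inf"][1], b["log10_sigma"][1]]
        if not self.fit_sigma:
            lo[1], hi[1] = b["log10_sigma"][0], b["log10_sigma"][0] + 1e-9
        for _ in range(self.n_processes):
            lo += [b["log10_delta_eps"][0], b["log10_tau"][0],
                   b["alpha"][0], b["gamma"][0]]
            hi += [b["log10_delta_eps"][1], b["log10_tau"][1],
                   b["alpha"][1], b["gamma"][1]]
        return np.asarray(lo), np.asarray(hi)

    def _initial_thetas(self, start_params, n_starts, rng) -> list[np.ndarray]:
        lo, hi = self._theta_bounds()
        f = self.spectrum.frequency
        thetas = []
        if start_params is not None:
            base = np.clip(_pack(start_params), lo, hi)
            thetas.append(base)
            for _ in range(max(0, n_starts - 1)):
                jit = base + rng.normal(0, 0.08, size=base.size) * (hi - lo)
                thetas.append(np.clip(jit, lo, hi))
            return thetas
        # tau guesses: one per loss peak visible in the fitted curve
        # (a practitioner's by-eye placement), remainder log-spaced over
        # the window
        from scipy.signal import find_peaks as _find_peaks

        log_f = np.log10(f)
        with np.errstate(divide="ignore"):
            log_t = np.log10(np.maximum(self._target, 1e-12))
        pk, _ = _find_peaks(log_t, prominence=0.05)
        peak_taus = sorted((-np.log10(2.0 * np.pi) - log_f[i] for i in pk),
                           reverse=True)[: self.n_processes]
        n_fill = self.n_processes - len(peak_taus)
        fill = list(np.linspace(log_f[0] - 0.5, log_f[-1] - 0.5, n_fill + 2)[1:-1])
        base_taus = np.asarray(sorted(peak_taus + [-v for v in fill], reverse=True))

        eps_inf0 = max(1.0, float(np.min(self.spectrum.eps_real)))
        de0 = max(0.1, float(np.ptp(self.spectrum.eps_real)))
        for s in range(max(1, n_starts)):
            taus = base_taus.copy()
            if s > 0:
                taus = taus + rng.normal(0, 0.4, size=taus.size)
            theta = [eps_inf0, -10.5 + (rng.normal(0, 1.0) if s > 0 else 0.0)]
            for k in range(self.n_processes):
                de_k = de0 / max(1, self.n_processes)
                if s > 0:
                    de_k *= math.exp(rng.normal(0, 0.5))
                theta += [np.log10(max(de_k, 0.05)), taus[k], 0.9, 0.9]
            thetas.append(np.clip(np.asarray(theta), lo, hi))
        return thetas

    # -- public ------------------------------------------------------------

    def fit(self, start_params: DielectricModel | None = None,
            n_starts: int = 8, seed: int | None = None,
            tether: bool = False,
            raise_on_failure: bool = False) -> DielectricFitResult:
        """Weighted least squares in the chosen representation.

        Multistart (seeded) with best-residual selection; with
        ``start_params`` the given model seeds the first start and
        jittered copies the rest.  ``tether=True`` (continuation mode,
        requires ``start_params``) adds a weak penalty keeping each
        process's strength and shape near the starting model; see
        ``_TETHER_SCALES``.
        """
        rng = np.random.default_rng(seed)
        lo, hi = self._theta_bounds()
        theta_ref = _pack(start_params) if start_params is not None else None
        if tether and theta_ref is None:
            raise ValueError("tether requires start_params")
        fun = (self._residuals if not tether
               else lambda th: self._tethered_residuals(th, theta_ref))
        best = None
        any_success = False
        for theta0 in self._initial_thetas(start_params, n_starts, rng):
            try:
                sol = least_squares(
                    fun, theta0, bounds=(lo, hi), method="trf",
                    x_scale="jac", max_nfev=4000)
            except Exception:
                continue
            any_success = any_success or sol.success
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailedError("all fit attempts raised")

        model = _unpack(best.x, self.n_processes)
        resid = self._residuals(best.x)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        dof = max(1, resid.size - best.x.size)
        try:
            JTJ = best.jac.T @ best.jac
            cov = np.linalg.pinv(JTJ) * (2.0 * best.cost / dof)
        except Exception:
            cov = None

        warns = []
        taus = np.array([p.tau_hn for p in model.processes])
        if taus.size >= 2 and np.any(np.abs(np.diff(np.log10(taus))) < 0.15):
            warns.append("processes closer than 0.15 decades in tau; "
                         "n_processes may exceed the resolvable peaks")
        result = DielectricFitResult(
            model, self.representation, best.x, cov, rms,
            n_starts_used=n_starts, converged=any_success, warnings_=warns)
        if not any_success and raise_on_failure:
            raise FitFailedError("fit failed to converge", best=result)
        return result


def fit_spectrum(spectrum: DielectricSpectrum, n_processes: int = 3,
                 representation: str = "tan_delta",
                 start_params: DielectricModel | None = None,
                 bounds: dict | None = None, n_starts: int = 8,
                 seed: int | None = None) -> DielectricFitResult:
    """Functional wrapper around ``DielectricSpectrumModel(...).fit(...)``."""
    model = DielectricSpectrumModel(
        spectrum, n_processes=n_processes, representation=representation,
        bounds=bounds)
    return model.fit(start_params=start_params, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# temperature series


@dataclass
class RelaxationMap:
    """Per-process tau_max versus temperature, plus the kink verdict."""

    processes: dict[int, list[tuple[float, float]]]  # process -> [(T degC, tau_max s)]
    kink_temperature: float | None = None
    fits: dict[float, DielectricFitResult] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for proc, series in self.processes.items():
            fitcols = {}
            for T, tm in series:
                res = self.fits.get(T)
                if res is not None and proc <= len(res.model.processes):
                    p = res.model.processes[proc - 1]
                    fitcols = {"delta_eps": p.delta_eps, "alpha": p.alpha,
                               "gamma": p.gamma, "sigma": res.model.sigma}
                rows.append({"process": proc, "T_C": T, "tau_max_s": tm, **fitcols})
        return pd.DataFrame(rows).sort_values(["process", "T_C"]).reset_index(drop=True)

    def tau_of(self, process: int) -> tuple[np.ndarray, np.ndarray]:
        series = sorted(self.processes[process])
        return (np.array([t for t, _ in series]), np.array([v for _, v in series]))


def build_relaxation_map(spectra: list[DielectricSpectrum], n_processes: int = 3,
                         representation: str = "tan_delta",
                         n_starts: int = 8, seed: int | None = None,
                         bounds: dict | None = None,
                         kink_process: int = 1) -> RelaxationMap:
    """Fit a temperature series with continuation and map tau_max(T).

    The series is fitted from the highest temperature downward: there all
    processes sit well inside the frequency window, and each converged
    model initialises the next (cooler) temperature, so a slow process
    can be tracked as its loss peak walks out of the window.  Process
    identity is assigned by tau ordering (process 1 slowest).  Fits whose
    taus come closer than 5% are flagged and both candidates reported.
    """
    if len(spectra) < 4:
        raise ValueError("need at least 4 temperatures for a relaxation map")
    ordered = sorted(spectra, key=lambda s: -s.temperature)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seeds = ss.generate_state(len(ordered))

    processes: dict[int, list[tuple[float, float]]] = {k + 1: [] for k in range(n_processes)}
    fits: dict[float, DielectricFitResult] = {}
    flags: list[str] = []
    prev_model = None
    for spec, sd in zip(ordered, seeds):
        sm = DielectricSpectrumModel(
            spec, n_processes=n_processes, representation=representation,
            bounds=bounds)
        res = sm.fit(start_params=prev_model,
                     n_starts=n_starts if prev_model is None else max(3, n_starts // 2),
                     tether=prev_model is not None,
                     seed=int(sd % (2 ** 31)))
        fits[spec.temperature] = res
        taus = np.array([p.tau_hn for p in res.model.processes])
        if taus.size >= 2:
            close = np.abs(np.diff(np.log10(taus))) < np.log10(1.05)
            if np.any(close):
                flags.append(
                    f"T={spec.temperature:g}C: tau ordering ambiguous, candidates "
                    + ", ".join(f"{t:.3g}s" for t in taus))
        for k, tm in enumerate(res.tau_max, start=1):
            processes[k].append((spec.temperature, tm))
        prev_model = res.model
    for k in processes:
        processes[k].sort()

    rmap = RelaxationMap(processes=processes, fits=fits, flags=flags)
    if len(processes.get(kink_process, [])) >= 6:
        rmap.kink_temperature = detect_kink(rmap, process=kink_process)
    return rmap


def detect_kink(rmap: RelaxationMap, process: int = 1) -> float | None:
    """Breakpoint test of log10(tau_max) versus 1/T for one process.

    Fits one straight line against two lines joined at a scanned
    breakpoint in Arrhenius coordinates and reports the break temperature
    (degC) when the two-line model wins on BIC; None otherwise.
    """
    T, tau = rmap.tau_of(process)
    if T.size < 6:
        raise ValueError("kink test needs at least 6 temperatures")
    x = 1.0 / (T + 273.15)
    res = detect_breakpoint(x, np.log10(tau))
    if res.breakpoint is None:
        return None
    return float(1.0 / res.breakpoint - 273.15)
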