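"""Study orchestration: run the three modalities and aggregate the verdicts.

``run_study`` executes the SAXS phase-diagram stage, the dielectric
relaxation-map stage and the FTIR trend stage over one sample's series,
estimates a phase-transition interval from each modality, intersects the
three intervals into a consensus, and writes a consolidated report.
``compare_excess_water`` contrasts two reports (with/without excess
water): per-process relaxation-time ratios, carbonyl-ratio trend
directions, and the presence of the OH-population discontinuity.

Stage failures are isolated: a modality that errors is logged and
reported missing, never aborting the study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .dielectric import DielectricSpectrum, RelaxationMap, build_relaxation_map
from .ftir import (FTIRSpectrum, band_center_trend, carbonyl_ratio,
                   fit_band_series, series_discontinuity, water_fractions)
from .saxs import DEFAULT_RULES, PhaseDiagram, SAXSPattern, build_phase_diagram

__all__ = ["StudyConfig", "StudyReport", "ComparisonResult",
           "run_study", "run_study_from_scenario", "compare_excess_water"]

log = logging.getLogger("mesokit.pipeline")


class ConfigError(ValueError):
    """Invalid study configuration; raised before any stage runs."""


@dataclass
class StudyConfig:
    """Inputs and knobs of one study run.

    Series may be given in memory (``*_series``) or as manifest paths
    (``*_manifest``); in-memory takes precedence.
    """

    name: str = "study"
    saxs_series: list[SAXSPattern] | None = None
    bds_series: list[DielectricSpectrum] | None = None
    ftir_series: list[FTIRSpectrum] | None = None
    saxs_manifest: str | None = None
    bds_manifest: str | None = None
    ftir_manifest: str | None = None
    rules: tuple = DEFAULT_RULES
    tolerance: float = 0.015
    min_prominence: float = 0.01
    n_processes: int = 3
    representation: str = "tan_delta"
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.tolerance <= 0.05:
            raise ConfigError("tolerance must lie in (0, 0.05]")
        if not 1 <= self.n_processes <= 4:
            raise ConfigError("n_processes must lie in 1..4")
        any_input = False
        for kind in ("saxs", "bds", "ftir"):
            series = getattr(self, f"{kind}_series")
            manifest = getattr(self, f"{kind}_manifest")
            if series is not None and len(series) == 0:
                raise ConfigError(f"{kind} series is empty; remove it or supply data")
            if manifest is not None:
                p = Path(manifest)
                if not p.exists():
                    raise ConfigError(f"{kind} manifest not found: {manifest}")
                if mio.read_manifest(p).empty:
                    raise ConfigError(
                        f"{kind} manifest {manifest} lists no files; "
                        "populate it or drop the stage")
            any_input = any_input or series is not None or manifest is not None
        if not any_input:
            raise ConfigError("no input series or manifests configured")

    def series(self, kind: str):
        s = getattr(self, f"{kind}_series")
        if s is not None:
            return s
        m = getattr(self, f"{kind}_manifest")
        if m is not None:
            return mio.load_series(m, kind)
        return None


@dataclass
class StudyReport:
    """Consolidated per-sample results; every verdict carries its numbers."""

    name: str
    water_wt: float = float("nan")
    phase_diagram: PhaseDiagram | None = None
    coexistence_window: tuple[float, float] | None = None
    relaxation_map: RelaxationMap | None = None
    kink_temperature: float | None = None
    ftir_trends: dict = field(default_factory=dict)
    phi_series: pd.DataFrame | None = None
    phi_discontinuity: float | None = None
    carbonyl_series: pd.DataFrame | None = None
    carbonyl_direction: str | None = None
    transition_intervals: dict = field(default_factory=dict)
    consensus_interval: tuple[float, float] | None = None
    disagreement: bool = False
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "water_wt": self.water_wt,
            "coexistence_window": self.coexistence_window,
            "kink_temperature": self.kink_temperature,
            "phi_discontinuity": self.phi_discontinuity,
            "carbonyl_direction": self.carbonyl_direction,
            "transition_intervals": {k: list(v) for k, v in
                                     self.transition_intervals.items()},
            "consensus_interval": self.consensus_interval,
            "disagreement": self.disagreement,
            "ftir_trends": {k: {"discontinuity": v.discontinuity,
                                "temperatures": v.temperatures.tolist(),
                                "values": v.values.tolist()}
                            for k, v in self.ftir_trends.items()},
            "relaxation_map": (
                {str(k): v for k, v in self.relaxation_map.processes.items()}
                if self.relaxation_map else None),
            "carbonyl_series": (json.loads(
                self.carbonyl_series.to_json(orient="records"))
                if self.carbonyl_series is not None else None),
            "errors": self.errors,
        }
        return json.dumps(payload, indent=2)


def _saxs_stage(report: StudyReport, series, cfg: StudyConfig, step: float) -> None:
    diagram = build_phase_diagram(series, rules=cfg.rules, tolerance=cfg.tolerance,
                                  min_prominence=cfg.min_prominence)
    report.phase_diagram = diagram
    report.coexistence_window = diagram.coexistence_window()
    if report.coexistence_window is not None:
        report.transition_intervals["saxs"] = report.coexistence_window


def _bds_stage(report: StudyReport, series, cfg: StudyConfig, step: float) -> None:
    rmap = build_relaxation_map(series, n_processes=cfg.n_processes,
                                representation=cfg.representation, seed=cfg.seed)
    report.relaxation_map = rmap
    report.kink_temperature = rmap.kink_temperature
    if rmap.kink_temperature is not None:
        report.transition_intervals["bds"] = (
            rmap.kink_temperature - step, rmap.kink_temperature + step)


def _ftir_stage(report: StudyReport, series, cfg: StudyConfig, step: float) -> None:
    # carbonyl and CH centres drift with temperature -> free fits;
    # the three broad OH populations overlap heavily -> tethered fits
    # (centres/widths pinned across the series, amplitudes linear)
    fits = {
        "carbonyl": fit_band_series(series, "carbonyl", seed=cfg.seed),
        "ch_stretch": fit_band_series(series, "ch_stretch", seed=cfg.seed),
        "oh_stretch": fit_band_series(series, "oh_stretch", seed=cfg.seed,
                                      mode="tethered"),
    }
    for region, tf in fits.items():
        for T, fit in tf:
            log.debug("T=%gC %s fit:\n%s", T, region, fit.summary())
    phi_rows, co_rows = [], []
    for (T, oh_fit), (_, co_fit) in zip(fits["oh_stretch"], fits["carbonyl"]):
        wf = water_fractions(oh_fit)
        phi_rows.append({"T_C": T, "phi_strong": wf.phi_strong,
                         "phi_less": wf.phi_less, "phi_weak": wf.phi_weak})
        cr = carbonyl_ratio(co_fit)
        co_rows.append({"T_C": T, "amplitude_ratio": cr.amplitude_ratio,
                        "area_ratio": cr.area_ratio})
    report.phi_series = pd.DataFrame(phi_rows)
    report.carbonyl_series = pd.DataFrame(co_rows)

    for label in ("CH2_sym", "CH2_asym", "CH_methylene"):
        report.ftir_trends[label] = band_center_trend(fits["ch_stretch"], label)
    phi_trend = series_discontinuity(report.phi_series["T_C"],
                                     report.phi_series["phi_strong"])
    report.ftir_trends["phi_strong"] = phi_trend
    report.phi_discontinuity = phi_trend.discontinuity

    slope = np.polyfit(report.carbonyl_series["T_C"],
                       report.carbonyl_series["amplitude_ratio"], 1)[0]
    report.carbonyl_direction = "increasing" if slope > 0 else "decreasing"

    candidates = [phi_trend.discontinuity,
                  report.ftir_trends["CH_methylene"].discontinuity]
    candidates = [c for c in candidates if c is not None]
    if candidates:
        t = float(np.mean(candidates))
        report.transition_intervals["ftir"] = (t - step, t + step)


def run_study(config: StudyConfig) -> StudyReport:
    """Run every configured stage, aggregate transition estimates, and
    (optionally) write the report tree under ``config.outdir``."""
    config.validate()
    report = StudyReport(name=config.name)

    stages = {"saxs": _saxs_stage, "bds": _bds_stage, "ftir": _ftir_stage}
    for kind, stage in stages.items():
        try:
            series = config.series(kind)
        except Exception as exc:  # manifest/file problems
            report.errors[kind] = f"loading failed: {exc}"
            log.error("%s stage input failed: %s", kind, exc)
            continue
        if series is None:
            continue
        if report.water_wt != report.water_wt:  # NaN
            report.water_wt = series[0].water_wt
        temps = sorted(s.temperature for s in series)
        step = float(np.median(np.diff(temps))) if len(temps) > 1 else 0.0
        try:
            stage(report, series, config, step)
            log.info("%s stage complete", kind)
        except Exception as exc:
            report.errors[kind] = str(exc)
            log.error("%s stage failed: %s", kind, exc)

    intervals = list(report.transition_intervals.values())
    if intervals:
        lo = max(i[0] for i in intervals)
        hi = min(i[1] for i in intervals)
        if lo <= hi:
            report.consensus_interval = (lo, hi)
        else:
            report.disagreement = True

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{config.name}_report.json").write_text(report.to_json())
        if report.phase_diagram is not None:
            report.phase_diagram.to_frame().to_csv(
                out / f"{config.name}_phase_diagram.csv", index=False)
        if report.relaxation_map is not None:
            report.relaxation_map.to_frame().to_csv(
                out / f"{config.name}_relaxation_map.csv", index=False)
        if report.phi_series is not None:
            report.phi_series.to_csv(out / f"{config.name}_phi.csv", index=False)
        if report.carbonyl_series is not None:
            report.carbonyl_series.to_csv(
                out / f"{config.name}_carbonyl.csv", index=False)
    return report


def run_study_from_scenario(scenario, seed: int | None = None,
                            modalities: tuple[str, ...] = ("saxs", "bds", "ftir"),
                            outdir: str | None = None) -> StudyReport:
    """Generate a scenario's series in memory and run the full study."""
    from . import scenarios as syn
    cfg = StudyConfig(name=scenario.name,
                      seed=scenario.seed if seed is None else seed,
                      outdir=outdir)
    if "saxs" in modalities:
        cfg.saxs_series = syn.gen_saxs_series(scenario, seed=seed)
    if "bds" in modalities:
        cfg.bds_series = syn.gen_bds_series(scenario, seed=seed)
    if "ftir" in modalities:
        cfg.ftir_series = syn.gen_ftir_series(scenario, seed=seed)
    return run_study(cfg)


@dataclass
class ComparisonResult:
    """Two-sample comparison, sample a versus sample b."""

    tau_ratios: pd.DataFrame          # process, T_C, tau_a, tau_b, ratio
    all_processes_faster_in_b: bool
    carbonyl_directions: tuple[str | None, str | None]
    carbonyl_opposite: bool
    phi_discontinuity: tuple[float | None, float | None]

    def to_json(self) -> str:
        return json.dumps({
            "tau_ratios": json.loads(self.tau_ratios.to_json(orient="records")),
            "all_processes_faster_in_b": self.all_processes_faster_in_b,
            "carbonyl_directions": list(self.carbonyl_directions),
            "carbonyl_opposite": self.carbonyl_opposite,
            "phi_discontinuity": list(self.phi_discontinuity),
        }, indent=2)


def compare_excess_water(report_a: StudyReport, report_b: StudyReport) -> ComparisonResult:
    """Contrast two studies at their common temperatures.

    ``tau_ratios`` holds tau_max(a)/tau_max(b) per process and common
    temperature; swapping the arguments yields elementwise reciprocals.
    """
    if report_a.relaxation_map is None or report_b.relaxation_map is None:
        raise ValueError("both reports need a relaxation map")
    rows = []
    procs = sorted(set(report_a.relaxation_map.processes)
                   & set(report_b.relaxation_map.processes))
    for p in procs:
        ta = dict(report_a.relaxation_map.processes[p])
        tb = dict(report_b.relaxation_map.processes[p])
        common = sorted(set(ta) & set(tb))
        for T in common:
            rows.append({"process": p, "T_C": T, "tau_a": ta[T], "tau_b": tb[T],
                         "ratio": ta[T] / tb[T]})
    if not rows:
        raise ValueError("reports share no common temperatures")
    df = pd.DataFrame(rows)
    dirs = (report_a.carbonyl_direction, report_b.carbonyl_direction)
    return ComparisonResult(
        tau_ratios=df,
        all_processes_faster_in_b=bool((df["ratio"] > 1.0).all()),
        carbonyl_directions=dirs,
        carbonyl_opposite=(None not in dirs and dirs[0] != dirs[1]),
        phi_discontinuity=(report_a.phi_discontinuity, report_b.phi_discontinuity),
    )
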