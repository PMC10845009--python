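"""Shared fixtures: scenario presets and their (expensive) fitted stages.

Everything is generated at test time from the scenario schedules; the
fixtures cache the slow fitting stages at session scope so several test
modules can interrogate the same maps and band fits.
"""

from __future__ import annotations

import numpy as np
import pytest

import mesokit as mk


@pytest.fixture(scope="session")
def m70():
    return mk.m70_w30(seed=0)


@pytest.fixture(scope="session")
def m55():
    return mk.m55_w45(seed=0)


@pytest.fixture(scope="session")
def saxs70():
    """M70-W30 SAXS temperature series, the seed used throughout."""
    return mk.gen_saxs_series(mk.m70_w30(seed=7), seed=7)


@pytest.fixture(scope="session")
def bds_maps():
    """Fitted relaxation maps for both presets (seed 2, 0.5% noise)."""
    maps = {}
    for name, fn in (("M70", mk.m70_w30), ("M55", mk.m55_w45)):
        sc = fn(seed=2)
        spectra = mk.gen_bds_series(sc, seed=2)
        maps[name] = (sc, mk.build_relaxation_map(spectra, n_processes=3, seed=2))
    return maps


@pytest.fixture(scope="session")
def ftir_series():
    return {"M70": mk.gen_ftir_series(mk.m70_w30(seed=6), seed=6),
            "M55": mk.gen_ftir_series(mk.m55_w45(seed=6), seed=6)}


@pytest.fixture(scope="session")
def ftir_fits(ftir_series):
    """Per-region band fits across temperature for both presets."""
    out = {}
    for name, series in ftir_series.items():
        fits = {}
        for region in ("carbonyl", "ch_stretch", "oh_stretch"):
            fits[region] = [
                (s.temperature, mk.fit_band(s, region, seed=6 + k))
                for k, s in enumerate(sorted(series, key=lambda s: s.temperature))]
        out[name] = fits
    return out


def scheduled_tau_max(scenario, process: int, temperatures) -> np.ndarray:
    """Ground-truth loss-peak time of one scheduled process."""
    ps = scenario.bds.processes[process - 1]
    return np.array([
        mk.HNProcess(ps.delta_eps, ps.tau_hn(t), ps.alpha, ps.gamma).tau_max
        for t in temperatures])
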