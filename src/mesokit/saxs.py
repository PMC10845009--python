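"""SAXS powder-pattern indexing of lyotropic liquid-crystal phases.

A 1-D scattering curve from a lipid-water mesophase shows a small set of
Bragg reflections whose relative positions identify the phase: the
double-diamond bicontinuous cubic Pn3m gives spacing ratios
sqrt2:sqrt3:sqrt4:sqrt6:sqrt8:sqrt9, the reverse hexagonal H_II gives
1:sqrt3:sqrt4, and so on.  This module detects peaks, assigns phases from
those ratio patterns, converts peak positions to lattice parameters, and
assembles a temperature-composition phase diagram including the
excess-water boundary (the hydration above which the lattice parameter
stops swelling because additional water no longer enters the mesophase).

Scattering vectors are handled in nm^-1 internally; readers accept
angstrom^-1 with a unit flag (values are multiplied by 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "SAXSPattern", "PeakSet", "RatioRule", "PhaseAssignment", "PhaseDiagram",
    "AmbiguousPeaksError", "UnindexedError", "DegenerateGeometryError",
    "PN3M", "HII", "IA3D", "IM3M", "LALPHA", "DEFAULT_RULES", "ALL_RULES",
    "detect_peaks", "index_phase", "fit_lattice_parameter",
    "detect_excess_water_boundary", "build_phase_diagram",
]


class AmbiguousPeaksError(ValueError):
    """Too few peaks to attempt a phase assignment."""


class UnindexedError(ValueError):
    """No supported ratio rule matches the observed peak set."""


class DegenerateGeometryError(ValueError):
    """Lattice-parameter regression produced a non-positive slope."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SAXSPattern:
    """One azimuthally averaged scattering curve at a (T, water wt%) state point."""

    q: np.ndarray           # scattering vector, nm^-1, strictly increasing
    intensity: np.ndarray   # nonnegative, arbitrary units
    temperature: float      # degC
    water_wt: float         # water mass fraction, percent

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or q.shape != i.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(q) > 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensity must be nonnegative")
        if not 0.0 <= self.water_wt <= 100.0:
            raise ValueError("water_wt must lie in [0, 100]")


@dataclass(frozen=True)
class PeakSet:
    """Extracted Bragg peak positions (nm^-1) with their prominences."""

    positions: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        pr = np.asarray(self.prominences, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "prominences", pr)
        if p.shape != pr.shape:
            raise ValueError("positions and prominences must have equal length")
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("positions must be sorted ascending")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class RatioRule:
    """Allowed-reflection pattern of one phase.

    ``moduli`` are the Miller moduli of the allowed reflections —
    sqrt(h^2+k^2+l^2) for cubic, sqrt(h^2+hk+k^2) for 2-D hexagonal,
    the order l for lamellar — so ``moduli/moduli[0]`` are the spacing
    ratios relative to the first allowed reflection.
    """

    phase_label: str
    moduli: tuple[float, ...]
    miller_indices: tuple[tuple[int, ...], ...]
    geometry: str  # cubic | hexagonal | lamellar

    def __post_init__(self) -> None:
        if list(self.moduli) != sorted(self.moduli):
            raise ValueError("moduli must be sorted ascending")
        if len(self.moduli) != len(self.miller_indices):
            raise ValueError("moduli and miller_indices must match in length")
        if self.geometry not in ("cubic", "hexagonal", "lamellar"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def spacing_ratios(self) -> np.ndarray:
        m = np.asarray(self.moduli, dtype=float)
        return m / m[0]

    def q_positions(self, lattice_parameter: float) -> np.ndarray:
        """Bragg positions (nm^-1) for a given lattice parameter (nm)."""
        m = np.asarray(self.moduli, dtype=float)
        if self.geometry == "hexagonal":
            return 4.0 * np.pi / (math.sqrt(3.0) * lattice_parameter) * m
        return 2.0 * np.pi / lattice_parameter * m


PN3M = RatioRule(
    "Pn3m",
    tuple(math.sqrt(n) for n in (2, 3, 4, 6, 8, 9)),
    ((1, 1, 0), (1, 1, 1), (2, 0, 0), (2, 1, 1), (2, 2, 0), (2, 2, 1)),
    "cubic",
)
HII = RatioRule(
    "HII",
    tuple(math.sqrt(n) for n in (1, 3, 4)),
    ((1, 0), (1, 1), (2, 0)),
    "hexagonal",
)
IA3D = RatioRule(
    "Ia3d",
    tuple(math.sqrt(n) for n in (6, 8, 14, 16, 20, 22)),
    ((2, 1, 1), (2, 2, 0), (3, 2, 1), (4, 0, 0), (4, 2, 0), (3, 3, 2)),
    "cubic",
)
IM3M = RatioRule(
    "Im3m",
    tuple(math.sqrt(n) for n in (2, 4, 6)),
    ((1, 1, 0), (2, 0, 0), (2, 1, 1)),
    "cubic",
)
LALPHA = RatioRule(
    "Lalpha",
    (1.0, 2.0, 3.0),
    ((0, 0, 1), (0, 0, 2), (0, 0, 3)),
    "lamellar",
)

#: rules tried by default (the phases occurring in the monolinolein system
#: over the temperature range of interest); Im3m and Lalpha are available
#: but off by default
DEFAULT_RULES: tuple[RatioRule, ...] = (PN3M, HII, IA3D)
ALL_RULES: tuple[RatioRule, ...] = (PN3M, HII, IA3D, IM3M, LALPHA)


@dataclass(frozen=True)
class PhaseAssignment:
    """Indexed phase(s) for one pattern: labels, matched peaks, lattice."""

    phases: tuple[str, ...]
    matched_peaks: dict[str, list[tuple[tuple[int, ...], float]]]  # phase -> [(hkl, q)]
    lattice_parameters: dict[str, float]  # phase -> a, nm
    residual: float                        # rms relative deviation of matched peaks
    unmatched: tuple[float, ...]

    @property
    def is_coexistence(self) -> bool:
        return len(self.phases) == 2


@dataclass
class PhaseDiagram:
    """(water wt%, T) -> phase map with per-temperature excess-water boundary."""

    grid: list[dict] = field(default_factory=list)
    excess_boundary: dict[float, float | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.grid:
            a = entry["assignment"]
            rows.append({
                "water_wt": entry["water_wt"],
                "temperature": entry["temperature"],
                "phase": "+".join(a.phases) if a is not None else "unindexed",
                "a_nm": ";".join(f"{a.lattice_parameters[p]:.4f}" for p in a.phases)
                        if a is not None else "",
                "residual": a.residual if a is not None else np.nan,
                "excess_water": entry["excess_water"],
            })
        return pd.DataFrame(rows)

    def coexistence_window(self, water_wt: float | None = None) -> tuple[float, float] | None:
        """First/last grid temperature where two phases are matched."""
        temps = sorted(
            e["temperature"] for e in self.grid
            if e["assignment"] is not None and e["assignment"].is_coexistence
            and (water_wt is None or e["water_wt"] == water_wt)
        )
        if not temps:
            return None
        return (temps[0], temps[-1])


# ---------------------------------------------------------------------------
# operations


def detect_peaks(
    pattern: SAXSPattern,
    min_prominence: float = 0.01,
    smoothing_window: int = 5,
) -> PeakSet:
    """Locate Bragg peaks in a 1-D pattern.

    The curve is smoothed with a centred moving average, local maxima are
    taken above a prominence threshold expressed as a fraction of the
    maximum intensity, and each position is refined by a three-point
    parabolic interpolation on the log of the smoothed intensity.
    """
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must lie in (0, 1)")
    y = pattern.intensity.astype(float)
    if y.size == 0 or np.ptp(y) == 0.0:
        return PeakSet(np.empty(0), np.empty(0))
    w = max(1, int(smoothing_window))
    if w > 1:
        kernel = np.ones(w) / w
        ys = np.convolve(y, kernel, mode="same")
    else:
        ys = y
    idx, props = find_peaks(ys, prominence=min_prominence * float(ys.max()))
    # moving-average padding can fabricate maxima at the grid edges
    keep = (idx >= w) & (idx <= y.size - 1 - w)
    idx, prom = idx[keep], props["prominences"][keep]
    if idx.size == 0:
        return PeakSet(np.empty(0), np.empty(0))

    q = pattern.q
    logy = np.log(np.maximum(ys, 1e-300))
    positions = []
    for i in idx:
        if 0 < i < y.size - 1:
            y0, y1, y2 = logy[i - 1], logy[i], logy[i + 1]
            denom = y0 - 2.0 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            positions.append(q[i] + delta * (q[min(i + 1, q.size - 1)] - q[i - 1]) / 2.0)
        else:
            positions.append(q[i])
    positions = np.asarray(positions)
    order = np.argsort(positions)
    return PeakSet(positions[order], prom[order])


def _match_rule(
    positions: np.ndarray, rule: RatioRule, anchor: float, tolerance: float,
) -> tuple[list[int], list[int], float, float]:
    """Greedy injective match of observed ratios against a rule's ratios.

    The anchor is the q position taken as the rule's first allowed
    reflection.  Returns (peak indices, rule reflection indices, rms
    relative deviation, completeness), where completeness is the matched
    fraction of the reflections the rule predicts inside the observed q
    span — it is what separates a genuine H_II set from the same three
    peaks read as a sparse Pn3m subset (1:sqrt3:sqrt4 is a subset of the
    Pn3m ratio list).
    """
    ratios = positions / anchor
    expected = rule.spacing_ratios
    matched_peaks: list[int] = []
    matched_refl: list[int] = []
    devs: list[float] = []
    used = set()
    for j, r in enumerate(expected):
        rel = np.abs(ratios - r) / r
        for i in np.argsort(rel):
            if rel[i] <= tolerance and i not in used:
                used.add(int(i))
                matched_peaks.append(int(i))
                matched_refl.append(j)
                devs.append(float(rel[i]))
                break
    rms = float(np.sqrt(np.mean(np.square(devs)))) if devs else np.inf
    predicted = anchor * expected
    lo = positions[0] * (1.0 - 2.0 * tolerance)
    hi = positions[-1] * (1.0 + 2.0 * tolerance)
    n_pred = int(np.sum((predicted >= lo) & (predicted <= hi)))
    completeness = len(matched_peaks) / max(1, n_pred)
    return matched_peaks, matched_refl, rms, completeness


def index_phase(
    peaks: PeakSet,
    rules: tuple[RatioRule, ...] = DEFAULT_RULES,
    tolerance: float = 0.015,
    two_phase: bool = True,
    min_coexist_peaks: int = 2,
) -> PhaseAssignment:
    """Assign phase label(s) to a peak set from its spacing-ratio pattern.

    Single-phase: the rule matching the most peaks (anchored at the first
    observed peak) wins; ties broken by lower rms deviation.  Two-phase
    mode then greedily re-indexes the leftover peaks against the
    remaining rules and reports coexistence when a second rule matches at
    least ``min_coexist_peaks`` of them.
    """
    if not 0.0 < tolerance <= 0.05:
        raise ValueError("tolerance must lie in (0, 0.05]")
    pos = peaks.positions
    if pos.size < 2:
        raise AmbiguousPeaksError(
            f"need at least 2 peaks to index a phase, got {pos.size}")

    def best_rule(candidates, leftover: set[int] | None = None):
        # anchor the rule's first allowed reflection on each candidate peak
        # (earlier anchors preferred on ties, so the first peak wins when
        # it belongs to the phase).  In second-phase mode (``leftover``
        # given) a rule may reuse peaks already assigned — reflections of
        # coexisting phases can overlap — but is ranked by how many
        # *leftover* peaks it explains.
        scored = []
        for rule in candidates:
            for ai in range(pos.size):
                mp, mr, rms, compl = _match_rule(pos, rule, pos[ai], tolerance)
                if len(mp) < 2 or 0 not in mr:  # anchor peak itself must match
                    continue
                n_new = (len(mp) if leftover is None
                         else sum(1 for i in mp if i in leftover))
                scored.append((n_new, len(mp), compl, -rms, -ai, rule, mp, mr))
        if not scored:
            return None
        scored.sort(key=lambda t: t[:5])
        return scored[-1]

    first = best_rule(rules)
    if first is None:
        raise UnindexedError("no rule matches at least 2 peaks")
    neg_rms, rule1, mp1, mr1 = first[3], first[5], first[6], first[7]

    phases = [rule1.phase_label]
    matched = {rule1.phase_label: [
        (rule1.miller_indices[j], float(pos[i])) for i, j in zip(mp1, mr1)]}
    rules_by_label = {rule1.phase_label: rule1}
    leftover_idx = [i for i in range(pos.size) if i not in set(mp1)]
    devs = [-neg_rms] if mp1 else []

    if two_phase and len(leftover_idx) >= min_coexist_peaks:
        remaining = tuple(r for r in rules if r.phase_label != rule1.phase_label)
        second = best_rule(remaining, leftover=set(leftover_idx))
        if second is not None and second[0] >= min_coexist_peaks:
            neg_rms2, rule2, mp2, mr2 = second[3], second[5], second[6], second[7]
            leftover_set = set(leftover_idx)
            phases.append(rule2.phase_label)
            # each peak belongs to exactly one phase: the second phase
            # keeps only the peaks the first one left over
            matched[rule2.phase_label] = [
                (rule2.miller_indices[j], float(pos[i]))
                for i, j in zip(mp2, mr2) if i in leftover_set]
            rules_by_label[rule2.phase_label] = rule2
            leftover_idx = [i for i in leftover_idx if i not in set(mp2)]
            devs.append(-neg_rms2)

    assignment = PhaseAssignment(
        phases=tuple(phases),
        matched_peaks=matched,
        lattice_parameters={},
        residual=float(np.sqrt(np.mean(np.square(devs)))),
        unmatched=tuple(float(pos[i]) for i in leftover_idx),
    )
    return fit_lattice_parameter(assignment, rules_by_label)


def fit_lattice_parameter(
    assignment: PhaseAssignment,
    rules_by_label: dict[str, RatioRule] | None = None,
) -> PhaseAssignment:
    """Least-squares lattice parameter per phase from matched peaks.

    Regresses q on the Miller modulus through the origin; the slope is
    2*pi/a for cubic and lamellar geometries and 4*pi/(sqrt(3)*a) for the
    2-D hexagonal lattice.
    """
    if rules_by_label is None:
        rules_by_label = {r.phase_label: r for r in ALL_RULES}
    lattice: dict[str, float] = {}
    rel_devs: list[float] = []
    for phase, pairs in assignment.matched_peaks.items():
        if not pairs:
            raise AmbiguousPeaksError(f"phase {phase} has no matched peaks")
        rule = rules_by_label[phase]
        mod_by_hkl = dict(zip(rule.miller_indices, rule.moduli))
        s = np.array([mod_by_hkl[hkl] for hkl, _ in pairs])
        qv = np.array([q for _, q in pairs])
        slope = float(np.dot(qv, s) / np.dot(s, s))
        if slope <= 0.0:
            raise DegenerateGeometryError(f"non-positive slope for phase {phase}")
        if rule.geometry == "hexagonal":
            lattice[phase] = 4.0 * np.pi / (math.sqrt(3.0) * slope)
        else:
            lattice[phase] = 2.0 * np.pi / slope
        rel_devs.extend(((qv - slope * s) / (slope * s)).tolist())
    residual = float(np.sqrt(np.mean(np.square(rel_devs))))
    return PhaseAssignment(
        phases=assignment.phases,
        matched_peaks=assignment.matched_peaks,
        lattice_parameters=lattice,
        residual=residual,
        unmatched=assignment.unmatched,
    )


def detect_excess_water_boundary(
    series: list[tuple[float, float]],
    tol: float = 0.02,
) -> float | None:
    """Find the hydration above which the lattice parameter plateaus.

    Fits a continuous increasing-then-constant two-segment model with the
    plateau slope fixed to zero, scanning the breakpoint over the
    composition grid.  Returns the breakpoint water wt% when the plateau
    spans at least two points, the pre-break slope is positive, the
    plateau is flat within ``tol`` (relative), and the two-segment model
    beats a single straight line on BIC; otherwise None.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 composition points")
    wt = np.array([p[0] for p in series], dtype=float)
    a = np.array([p[1] for p in series], dtype=float)
    if not np.all(np.diff(wt) > 0):
        raise ValueError("series must be sorted by water_wt, strictly increasing")
    n = wt.size

    # single-line reference
    A1 = np.column_stack([np.ones(n), wt])
    c1, *_ = np.linalg.lstsq(A1, a, rcond=None)
    sse1 = float(np.sum((a - A1 @ c1) ** 2))
    bic1 = n * np.log(max(sse1, 1e-300) / n) + 2 * np.log(n)

    best = None
    for i in range(1, n - 1):  # plateau spans points i..n-1 (>= 2 points)
        xb = wt[i]
        # y = a_p + b*min(wt - xb, 0)
        A = np.column_stack([np.ones(n), np.minimum(wt - xb, 0.0)])
        c, *_ = np.linalg.lstsq(A, a, rcond=None)
        sse = float(np.sum((a - A @ c) ** 2))
        if best is None or sse < best[0]:
            best = (sse, xb, c, i)
    assert best is not None
    sse2, xb, c, i = best
    bic2 = n * np.log(max(sse2, 1e-300) / n) + 3 * np.log(n)
    if bic2 >= bic1:
        return None
    if c[1] <= 0.0:
        return None
    plateau = a[i:]
    if np.ptp(plateau) > tol * float(np.mean(plateau)):
        return None
    return float(xb)


def build_phase_diagram(
    patterns: list[SAXSPattern],
    rules: tuple[RatioRule, ...] = DEFAULT_RULES,
    tolerance: float = 0.015,
    min_prominence: float = 0.01,
    plateau_tol: float = 0.01,
) -> PhaseDiagram:
    """Index every pattern of a (water wt%, T) grid and assemble the diagram.

    Unindexable state points are labelled ``unindexed`` rather than
    aborting the grid.  The excess-water boundary is located per
    temperature when the grid holds at least four compositions; the
    excess_water flag of each state point follows from it.
    """
    if not patterns:
        raise ValueError("no patterns given")
    diagram = PhaseDiagram()
    entries = []
    for pat in patterns:
        try:
            peaks = detect_peaks(pat, min_prominence=min_prominence)
            assignment = index_phase(peaks, rules=rules, tolerance=tolerance)
        except (AmbiguousPeaksError, UnindexedError, DegenerateGeometryError):
            assignment = None
        entries.append({
            "water_wt": pat.water_wt, "temperature": pat.temperature,
            "assignment": assignment, "excess_water": False,
        })

    temps = sorted({e["temperature"] for e in entries})
    for T in temps:
        row = sorted(
            (e for e in entries if e["temperature"] == T),
            key=lambda e: e["water_wt"])
        series = []
        for e in row:
            if e["assignment"] is not None and e["assignment"].lattice_parameters:
                # track the dominant (first) phase's lattice parameter
                phase = e["assignment"].phases[0]
                series.append((e["water_wt"], e["assignment"].lattice_parameters[phase]))
        boundary = None
        if len(series) >= 4:
            try:
                boundary = detect_excess_water_boundary(series, tol=plateau_tol)
            except ValueError:
                boundary = None
        diagram.excess_boundary[T] = boundary
        if boundary is not None:
            for e in row:
                e["excess_water"] = e["water_wt"] >= boundary
    diagram.grid = entries
    return diagram
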