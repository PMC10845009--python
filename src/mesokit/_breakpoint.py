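"""Single-breakpoint piecewise-linear model selection.

One routine serves both the Arrhenius-map kink test and the FTIR
band-centre / population discontinuity test, so a given (x, y) series
always yields the same verdict regardless of which modality asked.

The competing models are an ordinary straight line and two independent
straight segments split at a scanned interior position.  The two-segment
model covers both failure modes seen at a phase transition: a slope
change (kink) in Arrhenius coordinates, and a jump (discontinuity) in a
band-centre or population trend.  The split is scanned over the sample
positions — the data live on a coarse temperature grid and the
experiment cannot resolve a finer break — and the reported breakpoint is
the last x of the left segment.  Selection uses the Bayesian information
criterion, ``n*log(SSE/n) + k*log(n)``, with k = 2 for the line and
k = 5 for the split model (two intercepts, two slopes, one break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BreakpointResult", "detect_breakpoint"]


@dataclass(frozen=True)
class BreakpointResult:
    """Outcome of the line-versus-two-segment comparison."""

    breakpoint: float | None      # last x of the left segment; None if a line suffices
    sse_line: float
    sse_segments: float
    bic_line: float
    bic_segments: float
    slopes: tuple[float, float] | None   # (left, right) segment slopes

    @property
    def has_break(self) -> bool:
        return self.breakpoint is not None


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def detect_breakpoint(
    x: np.ndarray,
    y: np.ndarray,
    min_points: int = 6,
    min_segment: int = 3,
    min_evidence: float = 10.0,
) -> BreakpointResult:
    """Test a 1-D series for a single break (slope change or jump).

    Parameters
    ----------
    x, y : array-like, same length, x strictly monotone.
    min_points : smallest series the test will accept.
    min_segment : fewest samples per segment.
    min_evidence : required BIC margin of the two-segment model.  The
        break position is chosen by scanning, which inflates chance
        improvements, so a plain BIC comparison over-detects on short
        noisy series; 10 is the conventional "very strong evidence"
        threshold and the programmed transitions clear it by orders of
        magnitude.

    Returns
    -------
    BreakpointResult with ``breakpoint=None`` when the straight line is
    preferred.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < min_points:
        raise ValueError(f"breakpoint test needs at least {min_points} points, got {n}")
    dx = np.diff(x)
    if not (np.all(dx > 0) or np.all(dx < 0)):
        raise ValueError("x must be strictly monotone")
    if dx[0] < 0:  # analyse in ascending order
        x, y = x[::-1], y[::-1]

    sse1, _ = _line_fit(x, y)
    # a numerically perfect line (SSE at rounding level) never has a break
    floor = n * (1e-9 * max(1.0, float(np.max(np.abs(y))))) ** 2
    if sse1 <= floor:
        bic1 = n * np.log(max(sse1, 1e-300) / n) + 2 * np.log(n)
        return BreakpointResult(None, sse1, sse1, bic1, bic1, None)
    bic1 = n * np.log(sse1 / n) + 2 * np.log(n)

    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    for i in range(min_segment, n - min_segment + 1):  # left = x[:i], right = x[i:]
        sse_l, cl = _line_fit(x[:i], y[:i])
        sse_r, cr = _line_fit(x[i:], y[i:])
        sse = sse_l + sse_r
        if best is None or sse < best[0]:
            best = (sse, i, cl, cr)
    assert best is not None
    sse2, i, cl, cr = best
    bic2 = n * np.log(max(sse2, 1e-300) / n) + 5 * np.log(n)

    if bic2 + min_evidence < bic1:
        # a continuous kink: the two lines cross inside (or at the edge
        # of) the split gap — report the crossing.  A jump: they do not
        # cross there — report the last left-segment sample.
        xb = float(x[i - 1])
        dm = cl[1] - cr[1]
        if dm != 0.0:
            x_int = (cr[0] - cl[0]) / dm
            tol = 0.25 * (x[i] - x[i - 1])
            if x[i - 1] - tol <= x_int <= x[i] + tol:
                xb = float(np.clip(x_int, x[i - 1], x[i]))
        return BreakpointResult(
            breakpoint=xb, sse_line=sse1, sse_segments=sse2,
            bic_line=bic1, bic_segments=bic2,
            slopes=(float(cl[1]), float(cr[1])),
        )
    return BreakpointResult(
        breakpoint=None, sse_line=sse1, sse_segments=sse2,
        bic_line=bic1, bic_segments=bic2, slopes=None,
    )
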