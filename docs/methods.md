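# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## SAXS indexing

A 1-D powder pattern is reduced to peaks by a centred moving average
(default 5 points), `scipy.signal.find_peaks` with a prominence threshold
expressed as a fraction of the maximum intensity (default 0.01), and a
three-point parabolic refinement on the log of the smoothed intensity.
Peaks landing within one smoothing window of the grid edges are discarded:
the moving average pads with zeros and can fabricate maxima there.

Indexing works on spacing ratios, so it is scale-invariant by construction.
For each candidate phase rule the first allowed reflection is anchored on
each observed peak in turn and the remaining ratios are matched greedily and
injectively within a relative tolerance (default 1.5%, the largest value at
which the supported rule sets stay mutually distinguishable).  Ranking is by
(a) number of matched peaks, (b) completeness — the matched fraction of the
reflections the rule predicts inside the observed q span — then (c) rms
deviation, preferring earlier anchors on ties.  Completeness is what keeps a
three-peak reverse-hexagonal set (1:√3:√4) from being read as a sparse
subset of the Pn3̄m list (√2:√3:√4:√6:√8:√9), of which it is an exact ratio
subset; a genuine Pn3̄m pattern would show the other three reflections.

Two-phase decomposition is greedy: the best single phase is assigned first
and the leftovers are re-indexed against the remaining rules, reporting
coexistence when a second rule matches at least two leftover peaks.  In the
second pass a rule may *anchor* on an already-assigned peak — reflections of
coexisting phases genuinely overlap (the H_II (10) line can coincide with
the Pn3̄m (200) line) — but each peak is attributed to exactly one phase and
the second phase is ranked by the leftover peaks it explains.  An exhaustive
assignment search exists in the test suite as the oracle for this greedy
procedure; it is exponential in the peak count and not part of the library.

Lattice parameters come from a through-origin regression of q on the Miller
modulus.  The q unit is nm⁻¹ internally; readers accept Å⁻¹ via a flag.

The excess-water boundary fits an increasing-then-constant continuous
two-segment model (plateau slope fixed at zero), scanning the breakpoint
over the composition grid; the result is accepted only if the two-segment
model beats a single line by BIC, the pre-break slope is positive, the
plateau spans at least two points, and the plateau is flat within a
relative tolerance (default 0.02, several times the per-point noise a
lattice-parameter series typically carries — a genuine swelling trend
across a few wt% is an order of magnitude larger).

## Dielectric relaxation

The model is the standard HN sum plus dc conductivity (σ contributes to ε″
only; electrode polarization is not modelled).  Fits are nonlinear least
squares (`scipy.optimize.least_squares`, trf) on relative residuals over
the log-spaced frequency grid — uniform weight per decade — in either the
tan δ or the ε″ representation.  Internally Δε, τ and σ are parameterised
in log₁₀; approximate standard errors come from the Jacobian at the
solution by the delta method.

Two identifiability facts shaped the fitter:

* **tan δ is scale-blind.**  Multiplying Δε, ε∞ and σ by a common factor
  leaves ε″/ε′ unchanged, so a tan δ fit alone cannot fix the strengths.
  Three extra residuals anchor the model's high-frequency ε′ to the
  measured one, restoring the scale from data the spectrum already
  contains.
* **A process whose loss peak has left the window is degenerate on its
  flank.**  Δε, α, γ and τ trade off almost freely against 0.5%-level
  noise.  Series fitting therefore runs by continuation from the highest
  temperature downward — where all processes sit inside the 10⁻²–10⁶ Hz
  window — and each continuation fit adds a weak tether penalising drift
  of each process's (log₁₀ Δε, α, γ) from the neighbouring temperature
  (scales 0.05 decades, 0.02, 0.02 per step).  τ is never tethered: the
  Arrhenius trend is the measurement target and must come from the data.

Single-spectrum fits are multistart (default 8 seeded starts).  Initial τ
values are placed at the loss peaks actually visible in the fitted curve
(found by peak detection on the log-curve), with any remainder log-spaced
across the window; jittered copies explore around that.  Process identity
across temperature is assigned by τ ordering (process 1 slowest); fits
whose τ values come within 5% of each other are flagged and both
candidates reported.

The number of processes is user-set (three for this system); bounds on
α, γ are configuration.

## The shared breakpoint test

One routine serves the Arrhenius kink (slope change in 1/T–log₁₀ τ) and
the FTIR trend discontinuity (jump in a centre or population series): a
straight line is compared against two independent line segments split at a
scanned interior position.  Two segments cover both a kink and a jump; when
the fitted segments cross inside the split gap the crossing is reported
(kink), otherwise the last left-segment sample (jump).  Selection is by
BIC (k = 2 versus k = 5) with a required margin of 10 — the conventional
"very strong evidence" level — because the break position is chosen by
scanning, which inflates chance improvements on short noisy series; the
programmed transitions clear the margin by orders of magnitude.  A series
whose straight-line SSE is at numerical rounding level is declared
break-free outright.  Minimum segment length is 3 samples.

## FTIR deconvolution

All sub-bands are Gaussian (a Voigt or Lorentzian shape would change areas
by a few percent but none of the derived trends); each region is fitted
after removal of a linear baseline anchored on the mean of five edge points
per side (means, not medians, make the correction exactly idempotent), with
a residual linear baseline refitted jointly so an imperfect anchor cannot
bias areas.  Amplitudes are bounded nonnegative, centres to the window,
widths to (0.5 cm⁻¹, window span).  Components closer than a minimum
separation (default 2 cm⁻¹) are flagged as collapsed.

Series fitting has two modes.  *Free* fits every temperature
independently.  *Tethered* pins each component's centre and width to the
series median from a free first pass and refits only amplitudes and
baseline per temperature — a bounded linear problem.  The three OH
populations (σ ≈ 50–80 cm⁻¹, separations ≈ 2σ) overlap heavily enough that
free fits trade centre against area at the few-percent level; tethering
removes that trade-off and tightens Φx recovery by an order of magnitude,
at the price of assuming the band positions do not drift.  The pipeline
uses tethered mode for the OH region and free mode for the carbonyl and CH
regions, whose centres genuinely shift with temperature.  The OH region is
fitted over 3100–3700 cm⁻¹ separately from the CH region (2700–3100); the
carbonyl window (1680–1780) carries no explicit water-bending component.
The carbonyl ratio is reported on amplitudes ("intensity ratio"), with the
area ratio alongside.

## Synthetic generator

Scenario schedules are explicit functions of temperature: phase occupancy
with a linear amplitude crossfade across the transition window (50–62 °C,
padded 2 °C on each side so both phases are visible throughout the window);
lattice parameters linear in T and in hydration up to the excess-water
plateau (40 wt% at 30 °C, drifting −0.1 wt%/°C); per-process relaxation
times piecewise-Arrhenius (linear in 1/T) with the slope change at 55 °C;
band centres/areas linear in T with optional jumps above 55 °C.  The
slowest-process schedules span 0.1–100 s (M70-W30) and 0.001–0.1 s
(M55-W45); the remaining strengths, shapes and conductivities
(Δε = 60/8/3, α = 0.95/0.85/0.8, γ = 1/0.9/1, ε∞ = 3,
σ ≈ 10⁻¹¹ S/m) are order-of-magnitude working values, not measured ones.
Temperature grids are the experimental ones: SAXS every 4 °C over 30–66,
BDS every 3 °C over 31–70, FTIR every 3 °C over 28–70.

Noise is multiplicative Gaussian at 1% (SAXS), 0.5% (BDS, on ε′ and ε″
independently) and 0.5% (FTIR).  Everything is reproducible: one scenario
seed feeds per-modality child streams through `numpy` SeedSequence.

What the generator does **not** emulate — and hence what passing recovery
tests do not demonstrate about real data: instrumental resolution smearing
and form-factor modulation of Bragg intensities; electrode polarization and
sample-cell artefacts at low frequency; correlated (pink) noise;
non-Gaussian band shapes and water-vapour lines in the infrared;
temperature-dependent HN shape parameters.  Recovery results bound the
statistical error of the estimators under the assumed noise model, not the
systematic error of applying them to an instrument.

## Pipeline

Stages run isolated (a failing modality is logged and reported missing).
Each modality yields a transition interval — the SAXS coexistence window at
grid resolution, the BDS kink ± one temperature step, the FTIR
discontinuity consensus ± one step — and the study consensus is their
intersection, with an explicit disagreement flag when empty.  Reports are
deterministic given configuration and seed (no timestamps inside the
comparison payload).

## Problem sizes

The bundled tests and the acceptance script run the analyses at the
experimental series sizes (10 SAXS patterns, 14 dielectric spectra, 15
infrared spectra per sample; 81-point frequency grids, 2 cm⁻¹ infrared
resolution), which keeps a full two-sample study under a minute on one
core.

## Known limitations

* Two-phase SAXS decomposition is greedy; pathological peak sets with three
  or more coexisting phases are out of scope.
* The kink model is a single breakpoint with linear branches; no VFT
  fitting or glass-transition extrapolation.
* τ ordering can mislabel processes if two relaxations genuinely cross;
  the crossing is flagged, not resolved.
* The slowest process is recovered at the coldest temperatures only through
  the continuation tether; with shape parameters that genuinely vary fast
  in temperature its uncertainty there is larger than the formal errors
  suggest.
* JCAMP-DX input is not parsed; infrared spectra travel as two-column text.
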