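# mesokit

Analysis toolkit for lipid–water mesophases studied by three techniques at
once: small-angle X-ray scattering (SAXS), broadband dielectric spectroscopy
(BDS) and Fourier-transform infrared spectroscopy (FTIR).  It is written for
experimentalists who follow a lyotropic liquid crystal — here a
monolinolein–water system — through the phase transition from the
double-diamond bicontinuous cubic phase (*Pn3̄m*) to the reverse hexagonal
phase (H<sub>II</sub>), with and without excess water beyond the swelling
limit, and who want the three data streams reduced to one consistent picture:
which phase is present where, how fast the lipid relaxations are, and how the
water populations and the carbonyl interface respond.

## What it computes

**SAXS phase indexing.**  Bragg peaks are detected in 1-D powder patterns and
assigned from their spacing ratios: *Pn3̄m* reflections appear at
√2:√3:√4:√6:√8:√9 relative spacings, H<sub>II</sub> at 1:√3:√4, *Ia3̄d* at
√6:√8:√14:…  Lattice parameters follow from the regression of *q* on the
Miller modulus (*q* = 2π√(h²+k²+l²)/a for cubic, *q* = 4π√(h²+hk+k²)/(√3 a)
for hexagonal).  A grid of patterns becomes a temperature–composition phase
diagram with coexistence windows, and the excess-water boundary is located as
the hydration above which the lattice parameter stops swelling
(increasing-then-plateau piecewise fit).

**Dielectric relaxation.**  Spectra are modelled as a sum of Havriliak–Negami
(HN) processes plus dc conductivity,

    ε*(ω) = ε∞ + Σk Δεk / (1 + (iωτHN,k)^αk)^γk,    ε″cond = σ/(ω ε0),

with 0 < α ≤ 1 and 0 < αγ ≤ 1.  Fits run on the loss tangent
tan δ = ε″/ε′ (or on ε″), and the relaxation time at maximum loss follows
from the closed form

    τmax = τHN · [ sin(παγ/(2+2γ)) / sin(πα/(2+2γ)) ]^(1/α).

For a single Debye process the tan δ peak sits above the ε″ peak by the
factor (1 + Δε/εh)^½.  Temperature series are fitted by continuation (each
converged model seeds the next temperature) into per-process Arrhenius maps,
and a piecewise-linear test in (1/T, log₁₀ τmax) locates the kink at the
phase transition.

**FTIR band deconvolution.**  Spectral regions are decomposed into Gaussian
sub-bands on a linear baseline: the headgroup window (1000–1230 cm⁻¹, bands
Sn1/Sn2/Sn3), the ester carbonyl (1680–1780 cm⁻¹, H-bonded ≈1725 cm⁻¹ and
free ≈1736 cm⁻¹), the alkyl CH stretches (2700–3100 cm⁻¹) and the OH stretch
of water (3100–3700 cm⁻¹) split into three populations at ≈3300, ≈3450 and
≈3600 cm⁻¹.  Water fractions are Φx = Ax/Atot; the carbonyl free:H-bonded
intensity ratio and band-centre trends are tracked across temperature with
the same breakpoint test as the dielectric kink.

**Synthetic data.**  Because all three analyses are exercised end-to-end,
`mesokit.scenarios` generates SAXS/BDS/FTIR series from declarative
ground-truth schedules.  Two presets emulate the studied compositions:
`m70_w30()` (30 wt% water, no excess water — slowest relaxation 0.1–100 s,
population discontinuities at the transition) and `m55_w45()` (45 wt% water,
excess water present — every process faster, linear OH populations, opposite
carbonyl trend).

## Worked example

```python
import mesokit as mk

# index a cubic-phase pattern
scenario = mk.m70_w30(seed=7)
pattern = [p for p in mk.gen_saxs_series(scenario, seed=7)
           if p.temperature == 30][0]
assignment = mk.index_phase(mk.detect_peaks(pattern))
for phase in assignment.phases:
    print(phase, assignment.lattice_parameters[phase],
          len(assignment.matched_peaks[phase]))
```

prints `Pn3m 9.750 6`: six reflections at √2:√3:√4:√6:√8:√9 spacings index
the diamond cubic phase with lattice parameter 9.75 nm (residual 2×10⁻⁴).

```python
spectrum = [s for s in mk.gen_bds_series(mk.m70_w30(seed=2), seed=2)
            if s.temperature == 40][0]
result = mk.fit_spectrum(spectrum, n_processes=3, seed=2)
print(result.summary())
```

```
Havriliak-Negami spectrum fit
==============================================
representation: tan(delta)   processes: 3
rms relative residual: 6.421e-03
----------------------------------------------
parameter           estimate       std err
eps_inf                3.002         0.012
sigma              6.768e-12       9.9e-13
delta_eps_1            63.69           5.3
tau_hn_1               13.19          0.68
...
tau_max_1              13.19
tau_max_2           0.001163
tau_max_3          4.835e-06
```

Three processes are resolved; the slowest (τmax ≈ 13 s at 40 °C) is the one
that spans 0.1–100 s over the full temperature range without excess water.
`mk.build_relaxation_map` turns the whole series into per-process τmax(T)
curves and reports the Arrhenius kink near the phase transition, and
`mk.run_study_from_scenario` / `mk.compare_excess_water` aggregate all three
modalities into a study report with the with/without-excess-water verdicts.

A command-line layer mirrors the library:
`mesokit synth --preset m70-w30 --out data/` writes a full synthetic file
tree; `mesokit saxs index`, `mesokit bds map`, `mesokit ftir fit` and
`mesokit run` operate on such trees.

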