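# Methods

## Model and assumptions

The twin is a lumped-parameter hydraulic analogue of a craniospinal bench
operated in a supine position.  Working fluid is water (incompressible,
Newtonian, viscosity 1 mPa·s); CSF production and absorption are neglected
(their per-cycle volumes are orders of magnitude below the pulsatile
exchange), as are breathing, hydrostatic terms and any viscoelastic
("dynamic") compliance.  Compliance is purely static, supplied by two sealed
air chambers; resistance is purely laminar.

**Topology.** Four nodes. The piston pump injects the AV flow into node N1
(cranial compliance chamber).  Two parallel resistive paths connect N1 to the
cistern node N3: the parenchyma path (Valve 1 in series with the aqueduct;
the ventricular ICP sensor sits at the intermediate node N2) and Valve 2
(cranial subarachnoid space).  N3 drains through the series spinal canal
into node N4 (spinal compliance chamber).  The rigid parenchyma box stores no
volume, so N2 and N3 are purely algebraic nodes; the only state variables are
the two chamber air volumes.  With conductances `G_a` (sum of the two cranial
paths) and `G_c` (canal), the cistern pressure is the conductance-weighted
average `p₃ = (G_a·p₁ + G_c·p₄)/(G_a + G_c)`, and
`ICP = p₁ − Q_par·R_valve1`.

**Gas law.** Chamber pressure follows `p = p₀(V₀/V)^λ` in absolute units
(atmosphere 760 mmHg + gauge); all reported pressures are gauge.  Absolute
units are essential: evaluating the gas law at gauge ICP (~13 mmHg) would
require absurd air volumes.  λ defaults to 1.4 (adiabatic air) and may be
lowered to 1.0 (isothermal) for slow cycles.  The compliance formula
`C(p₁) = (1/λ)p₀^{1/λ}V₀p₁^{-(1+λ)/λ}` is the exact derivative of the gas
law; the test suite checks it against central finite differences to 1e-6
relative.

**Operating point.** The configured baseline ICP (default 12.68 mmHg) is
interpreted as the *running-mean* operating pressure — the quantity a bench
reports.  Because the pump's cumulative displaced volume has a nonzero time
average over the cycle, a system initialized at rest exactly at the baseline
settles onto a periodic orbit whose mean pressure is slightly higher (~0.2
mmHg for the default waveform).  `simulate` therefore pre-loads the chambers:
the initial common pressure is solved by Newton iteration so that the extra
air volume equals the pump's mean stored volume, making the cycle-mean
pressure of the orbit equal the baseline to well under 0.01 mmHg.  With a
zero pump input this reduces to the rest state.

## Driving waveform

Fig.-style AV curves are not tabulated anywhere, so the canonical source is a
parametric generator (a CSV reader accepts digitized curves).  The arterial
inflow is a baseline (650 ml/min) plus a Gaussian systolic lobe (peak 350
ml/min above baseline, center 0.20 s, σ = 0.06 s) — mean inflow ≈ 710
ml/min, a typical total cerebral blood flow.  The venous outflow is the
arterial curve circularly delayed by 0.12 s and Gaussian-smoothed with
σ = 0.10 s (venous Windkessel flattening), applied spectrally so the cycle
volume is conserved exactly.  After volume matching (mandatory uniform
scaling; an optional extra shift is configurable) the AV difference is scaled
so its caudal lobe carries exactly 0.8 ml.  These widths and delays were
chosen once, on physiological grounds, to give the canonical AV morphology: a
sharp systolic surge followed by a roughly twice-as-wide return lobe about an
eighth of a cycle later, with a caudal/cranial extremum ratio near 2:1.

The synthetic cervical-flow cohort emulates cardiac-gated PC-MRI recordings
of healthy young adults: a two-lobe template (caudal max 122.82 ml/min at
cycle start, cranial max −77.86 ml/min at 63% of the cycle, lobe volumes
0.385 ml each; lobe amplitudes are fixed-point corrected for wrapped-tail
overlap) with per-subject multiplicative amplitude jitter (σ = 15%,
reflecting reported cohort deviations of roughly a quarter of the mean) and
circular timing jitter (σ = 5% of the cycle).  Ultrasound flow-meter noise
maps the manufacturer accuracy `a` (±6 ml/min) to Gaussian noise with
σ = a/2, reading the accuracy statement as a ±2σ bound.  The generator does
**not** emulate beat-to-beat heart-rate variability, respiratory modulation,
measurement baseline wander or intra-subject waveform shape changes — so
passing cohort tests demonstrates correct statistics of amplitude/timing
spread, not realism of individual PC-MRI traces.

## Numerics

- Integrator: classical fixed-step RK4, `dt = period/2048` by default. A
  fixed step keeps cycle marks exact and results bit-reproducible; the
  two-state system is non-stiff at physiological parameters (transient time
  constant ≈ R·C ≈ 0.1–0.2 s).  The primary correctness gate is agreement
  within 1% (amplitude and phase) with the closed-form response of the
  linearized RC network, `H(ω) = (C_s/(C_c+C_s))/(1 + jω R_s C_c C_s/(C_c+C_s))`.
- Volume bookkeeping is exact by construction: `d(V₁+V₄)/dt = −Q_pump/60`,
  so a zero-net pump waveform cannot drift.  Waveforms with |net volume|
  > 1e-6 ml are refused (drift error), as are cam profiles built from them
  (closure error).
- Protocol mirror: two warm-up cycles are integrated and discarded before
  nine cycles are recorded, at 70 beats/min.
- Degenerate inputs: a flat flow waveform has no defined cranial-max phase
  (NaN); an ICP cycle without detectable pulse peaks yields NaN MWA/P2:P1;
  phase and peak ties break to the earliest sample.

## Calibration

The bench's valve settings are unreported; the twin recovers them from the
measured spinal-flow extrema by a deterministic bounded search: an 8×8
log-spaced grid over both resistances in [1e-4, 1] mmHg/(ml/min) followed by
Nelder–Mead refinement in log space (internal simulations at `dt =
period/512`, warm-up 2 + 2 recorded cycles; the reported fit re-simulates at
full resolution).  Resolution choices keep the whole fit at ~130 simulations
in a couple of seconds while extrema differ by < 0.5% between 512 and 2048
steps/cycle.

Identifiability: the two cranial paths share both endpoints, so the spinal
flow depends on them only through their parallel resistance.  The fit
therefore pins the parallel combination (reported as `r_parallel`); the
individual split is a free parameter that moves only the ICP tap between
Valve 1 and the aqueduct.  Parameter-recovery tests assert the parallel
combination, not the split.  Failure to reach the 5% relative tolerance is
reported (`converged=False` with residuals) rather than raised.

## Cam synthesis

Follower is idealized as a radial knife edge: `r(θ) = r_base + x(θ)` with
`x` the cumulative displaced volume over the piston area, normalized to zero
minimum; one cam revolution per cardiac cycle.  Roller-radius compensation
and pressure-angle analysis are out of scope.  Defaults (9 mm bore — the
2 ml-syringe class, 20 mm base radius) are placeholders for unreported bench
geometry.  The inverse check (central-difference differentiation of the
exported lift at the rotation speed) recovers the input flow to < 1% RMS at
256 samples/revolution.

## Metrics conventions

- Stroke volume: trapezoidal integral of the caudal (positive) lobe of the
  cycle-mean flow; under zero net volume this equals the cranial-lobe
  magnitude.
- Phase of the cranial-directed maximum: cycle re-anchored at the caudal
  maximum (0% = 100%), position of the global minimum in percent.
- ICP cycles are split minimum-to-minimum (peak detector with 70%-of-period
  minimum separation) and resampled to a common 0–100% grid; MWA is the
  height of the first pulse peak above the cycle-start minimum on the
  cycle-mean curve; P2:P1 the height ratio of the second to first peak.
  Peaks are *located* on a 5%-of-cycle moving-average smoothed copy but
  *measured* on the raw cycle-mean curve (heights on the smoothed curve would
  be biased low by a few percent).

## Compliance-share reporting

Percentage shares of the compliance budget are computed from the configured
values and rounded half-up: 0.31/1.15 → 27% cranial, 0.84/1.15 → 73% spinal.
Quoted distributions that pair 27% with 68% (summing to 95%) are not
reproducible from the values themselves; the package always reports the
computed shares.

## Problem sizes

Default runs use 256 samples per waveform cycle, 2048 integration steps per
cycle, 2 warm-up + 9 recorded cycles, and ~130 calibration simulations at
512 steps per cycle — a complete calibrate-and-validate pipeline finishes in
a few seconds on one CPU.

## Known limitations

Static compliance only: the twin reproduces the early (~25–30% of cycle)
cranial-flow maximum characteristic of air-chamber benches, not the ~63% of
in vivo recordings — matching that timing requires viscoelastic (dynamic)
compliance, which is deliberately not modeled.  Its ICP pulse amplitude
(~1.4 mmHg MWA) is below typical bench values because the lumped parenchyma
path stores no volume; only the bound (< 5 mmHg) is meaningful.  No
spatially resolved flow, no shunt/implant elements, no posture changes.
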