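# Methods

This note records the models, numerical choices and limitations behind
`echobc`, in the order the pipeline applies them.

## Waveform model and cleaning

A Doppler examination yields, per site, the envelope (maximum) velocity
over one cardiac cycle, digitised as (t, v) samples. The package treats
one-cycle extraction as upstream work: a `VelocityWaveform` must already
span exactly one cycle (strictly increasing times, non-negative
velocities, ≥ 3 samples). Beat segmentation and spectrogram image
processing are out of scope.

**Smoothing.** Digitisation noise is removed with a centred local
least-squares quadratic fit (Savitzky–Golay-type), window default 7
samples; near the ends the window shrinks symmetrically, so the first and
last samples are fixed points. A quadratic preserves the amplitude of a
smooth systolic peak far better than a moving average, which matters
because every downstream quantity keys off peaks. Fitted values are
clamped at zero (envelopes are magnitudes). On a single-peak envelope the
filter cannot raise the global maximum; on flat-topped shapes with sharp
shoulders it can overshoot slightly — a known property of quadratic
filters, irrelevant for physiological envelopes.

**Period normalisation.** Heart rate varies between acquisitions, so each
cycle's time axis is linearly rescaled to a common reference period of
0.5 s (120 beats/min), velocities untouched. This makes sites comparable
but deliberately does not model the physiological change of waveform
*shape* with heart rate.

## Pressure and flow conversion

The clinical pressure estimate is the simplified Bernoulli relation
ΔP = 4v² (mmHg, v in m/s). The coefficient 4 is the rounded value of
½ρ·c with ρ = 1060 kg/m³ and c = 0.00750062 mmHg/Pa: exactly 3.9753, a
0.62% difference the package's tests pin. The Pa→mmHg constant is fixed
at 6 significant figures for bit-stable output. Published clinical tables
occasionally print ΔP values that disagree with 4v² on the printed
two-decimal velocity by a few hundredths of a mmHg (rounding of a
higher-precision velocity upstream); the package always computes 4v² from
the velocity it is given.

Flow is Q(t) = A·v_ave(t). Envelope velocity is a maximum over the sample
volume, so a profile assumption maps it to the cross-section average: at
the inlet a parabolic profile (v_ave = v/2), at outlets
envelope-equals-average. Patch areas come from measured diameters assuming
circular sections, or from contour/area–perimeter input via the geometry
module.

## Mass-consistent flow splitting

Because envelopes overestimate average velocity, the raw outlet flows are
inconsistent with the inlet. Three regimes are supported:

* **Full data** — all outlets are scaled by a single uniform factor so
  that the peak of their pointwise sum equals the peak inlet flow. Summing
  digitised curves requires a grid: all waveforms are linearly resampled
  onto a common uniform 1000-point grid, and *both* peaks (inlet and sum)
  are evaluated on that grid. Evaluating them on the same grid is what
  makes the contract exact — a sampled peak loses O(10⁻⁴) of its value
  when interpolated onto a non-nested grid, so mixing sampled and
  interpolated maxima would leave an artificial residual. After scaling,
  the relative mismatch of the two peaks is below 10⁻⁹.
* **Partial post-repair** (inlet + innominate only) — the innominate
  keeps the full-data uniform factor; the carotid and subclavian are
  imputed as pre-repair branch-to-innominate *peak* ratios times the
  scaled innominate; the descending aorta is the inlet waveform times a
  factor s solved so the summed outlet peak matches the inlet peak.
  Because phases differ, the peak of the sum is monotone but not linear
  in s; s is found by bisection on (0, 2] with tolerance 10⁻¹⁰. Peak
  ratios (not pointwise ratios) are used throughout, matching the
  peak-oriented character of the whole procedure.
* **Hypothetical healthy** — a configurable fraction (default 0.70, the
  lower end of the 70–80% range reported for healthy aortas) of the inlet
  waveform exits the descending aorta; the remainder divides among the
  branches by area ratio. Conservation is pointwise by construction and
  invariant to uniform area rescaling.

An optional, off-by-default strategy cyclically shifts each non-descending
outlet so its peak aligns with the inlet peak before scaling; it exists
for comparison studies only.

Steady boundary values are extracted at t*, the first time of the inlet
maximum; each outlet contributes its interpolated flow at t*. The written
inlet value is the **sum of the outlet values**, not the raw inlet peak,
so the steady CFD problem conserves mass exactly even when phase lags put
outlet values below their own peaks. (Published boundary-flow tables for
the partial regime can violate this — printed outlets summing above the
printed inlet — which is why the package enforces the contract itself.)
Lumped-parameter (Windkessel) outlet models are deliberately not offered:
they need calibration data this measurement protocol does not produce.

## Geometry

Hydraulic diameter D_h = 4A/P is used as "the" diameter of an irregular
lumen (it equals the geometric diameter for a circle, and published
severity tables satisfy it exactly, so the coarctation ratio
D_coarct : D_DAo uses hydraulic — not fitted-circle — diameters).
Contours are planar point lists in mm; area and perimeter come from the
validated polygon (shapely), equivalent to the shoelace formula and
summed segment lengths, orientation-independent. Self-intersecting or
degenerate contours are rejected. A convenience plane-cut (via trimesh)
sections an STL surface and feeds the largest closed contour to the same
metrics; a plane sweep reports the minimum-D_h section, since the
narrowest point of a coarctation is not known a priori. Outlet patches of
a CFD model are extruded by 10 × D_h to keep recirculation away from the
boundary.

## OpenFOAM case

The emitted dialect targets OpenFOAM 6: `flowRateInletVelocity` at the
inlet and `flowRateOutletVelocity` at each outlet, both with constant
`volumetricFlowRate` written as positive magnitudes (the built-in
conditions own the direction convention), `noSlip` walls, Newtonian
transport with ν = 3.78·10⁻⁶ m²/s, a backward (second-order implicit)
time scheme and a bounded second-order upwind convective scheme — the
specific scheme name (`linearUpwind grad(U)`) is this package's default,
as is the solver/relaxation block. Pressure is `zeroGradient` on all
patches with an internal reference (cell 0, value 0); a
zero-pressure-outlet variant is available for grid studies. File
generation is deterministic (fixed patch order, `%.6g` floats), so
regeneration from the same boundary spec is byte-identical, and the
bundled parser recovers every written flow value exactly. Solvers,
meshing and parallel decomposition are out of scope.

Solver output is kinematic pressure (p/ρ, m²/s²); multiplying by ρ and
0.00750062 gives mmHg.

## Grid independence

Between adjacent refinement levels (e.g. 0.5M → 2M → 4M cells), at every
shared sampling station, the assessment computes (a) the relative change
of the trapezoidal position-weighted mean pressure and (b) the relative
L2 and max-norm differences of the velocity profile after interpolating
the coarser mesh onto the finer positions. All three metrics must be at
or below the threshold (default 5%) — the conservative reading of a
"within 5%" criterion that does not say whether it applies to pressure or
velocity. Richardson extrapolation / formal GCI is beyond scope.

## Synthetic examinations

The generator emulates what the pipeline actually consumes: a
raised-cosine systolic pulse (amplitude renormalised so the sampled
maximum equals the nominal peak exactly), an exponential diastolic tail
(onset amplitude = tail fraction × peak at the systolic peak, decay
constant one period — large through a tight stenosis, small elsewhere), a
per-site cyclic phase lag (2–8% of the cycle, mimicking pulse transit),
and additive Gaussian noise clamped at zero. Defaults, chosen once:
100 samples/cycle (typical hand-digitisation density), systolic fraction
0.35, heart rate drawn per patient from 95–130 BPM with ±5 BPM per-site
jitter, site amplitudes and diameters at the magnitudes of a published
paediatric pre/post-repair examination, noise off unless requested.

Patients are *constructed to be recoverable*: after generating noise-free
waveforms, outlet velocities are rescaled so that the default processing
chain recovers exactly the nominal uniform factor (0.8243), and the
innominate amplitude of a partial examination is solved (bisection) so the
descending factor comes out at its nominal 0.5101; these values are stored
as ground truth and noise is added only afterwards. Noise-free recovery is
therefore exact to solver/float tolerance (≪ 10⁻⁴; through the
6-significant-digit text format, ~10⁻⁵). At 0.05 m/s envelope noise the
peak-ratio estimator is essentially unbiased but has per-replicate scatter
of roughly 2% (uniform factor) to 4% (descending factor) — maxima of noisy
curves are noisy — so recovery at that noise level is assessed on the
20-replicate mean, which lands well within 2% of truth.

What passing these tests does **not** show: the generator's envelope
family is idealised (no spectral broadening, no probe-angle error, no
beat-to-beat variability, no correlated digitisation error), so recovery
accuracy on real traces will be worse and dominated by acquisition
quality, not by this implementation.

## Degenerate inputs and tie-breaks

Equal velocity maxima resolve to the earliest time (peak systole is the
first systolic event). Zero summed outlet peak, zero innominate peak,
unsolvable descending factor, identically-zero reference profiles and
disjoint sampling ranges all raise typed errors rather than returning
NaN. Non-monotone sampled-line positions are sorted with a logged
warning; ragged rows fail with a line number.
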