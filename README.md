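# echobc

Doppler-echocardiography-driven boundary conditions and case setup for
patient-specific CFD of aortic coarctation.

## The problem

Coarctation of the aorta (CoA) is a congenital narrowing of the aorta whose
severity is judged by the pressure difference across the stenosis; repair is
usually indicated above a 20 mmHg peak-systolic difference. Patient-specific
CFD can supply that pressure difference non-invasively, but it needs velocity
boundary conditions. Where phase-contrast MRI is unavailable — the common
situation in resource-constrained clinics — the only velocity source is
Doppler transthoracic echocardiography, which yields per-site *envelope*
(maximum) velocity traces that are noisy, acquired at varying heart rate,
and mutually mass-inconsistent.

`echobc` turns digitised Doppler velocity–time envelopes plus vessel
cross-section measurements into:

* cleaned, period-normalised waveforms (local-quadratic smoothing; every
  cycle rescaled to 0.5 s ≡ 120 BPM so sites are comparable);
* simplified-Bernoulli pressure estimates, ΔP = 4v² (mmHg, v in m/s) —
  the coefficient 4 being ½ρ·(Pa→mmHg) = 3.9753 for blood, rounded;
* volumetric flow waveforms Q(t) = A·v_ave(t), with a parabolic-profile
  assumption at the inlet (v_ave = v/2) and envelope-equals-average at
  outlets;
* **mass-consistent** steady peak-systolic boundary flows under three data
  regimes: full examination (uniform outlet scaling so the peak of the
  summed outlet flow matches the peak inlet flow), partial post-repair
  examination (branch imputation from pre-repair ratios plus a solved
  descending-aorta factor), and a hypothetical healthy state (70% of flow
  through the descending aorta, branches split by area ratio);
* coarctation severity metrics from cross-sections: hydraulic diameter
  D_h = 4A/P and the coarctation ratio D_coarct : D_DAo;
* a ready-to-run OpenFOAM case skeleton (`flowRateInletVelocity` /
  `flowRateOutletVelocity` / `noSlip`, Newtonian blood with
  ν = 3.78·10⁻⁶ m²/s, ρ = 1060 kg/m³) and a reader for sampled
  post-processing output;
* a grid-independence report (5% criterion on station-mean pressure and
  interpolated velocity profiles between adjacent mesh refinements).

A seeded synthetic-examination generator (`echobc.synthetic`) emulates
single-cycle Doppler envelopes — raised-cosine systolic pulse, diastolic
tail, per-site phase lag, sampling noise — with stored ground-truth split
factors, so the whole pipeline is testable without clinical data.

## Worked example

```sh
python examples/02_boundary_conditions.py
```

```
uniform outlet scaling factor: 0.8222
(constructed ground truth:     0.8243)

steady peak-systolic boundary flows (1e-5 m^3/s):
  inlet                7.73
  innominate           4.43
  lcca                 0.83
  lsca                 0.96
  descending_aorta     1.52
the inlet value is the sum of the outlets, so the CFD problem
conserves mass exactly despite the envelope overestimation.

wrote 5 OpenFOAM files under scratch/example_case/
```

The factor 0.8222 is the uniform scaling applied to all outlet flow
waveforms so that the peak of their sum equals the peak inlet flow; on this
noisy synthetic patient it recovers the constructed truth (0.8243) to about
0.3%. The table lists the per-patch flow rates written into `0/U`; the
inlet entry is the sum of the outlets, so the steady problem is exactly
mass-conservative. The other examples cover waveform cleaning and Bernoulli
pressures (`01`), severity metrics (`03`, which prints hydraulic diameters
3.37/5.76/8.96/7.83 mm and ratios 0.43/0.74/1.14 for three repair states),
and the grid-independence check (`04`).

There is also a thin CLI over the same functions:

```sh
echobc gen-synthetic --scenario full_data --seed 1 --out patient/
echobc build-case --patient-dir patient/ --out run/
echobc geom-metrics --section coarct:8.08:9.59 --dao dao:48.25:24.66
```

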