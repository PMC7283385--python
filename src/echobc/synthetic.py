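"""Seeded synthetic Doppler examinations for end-to-end testing.

No public clinical dataset accompanies this problem, so every pipeline
stage is exercised on generated patients.  A waveform is modelled as a
raised-cosine systolic pulse plus an exponentially decaying diastolic tail
(the clinical "diastolic tail": continued forward flow through a stenosis
during diastole), cyclically phase-lagged per site, with optional additive
Gaussian noise clamped at zero (envelopes are magnitudes).

A :class:`SyntheticPatient` carries per-site waveforms, vessel diameters
and the *ground-truth* split factors its construction encoded, so
construct-then-recover tests can assert that the processing pipeline gets
the factors back.  Default site amplitudes and diameters follow the
magnitudes of a published pre/post-repair paediatric coarctation
examination (ascending aorta ≈ 1.3 m/s, 13 mm; coarctation jet ≈ 3.5 m/s
pre-repair; …) so fixtures are clinically plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import yaml

from .errors import InvalidParameterError
from .flow_split import CaseMode, SplitFactors, branch_ratios_from, conserve_mass_scale
from .waveforms import (
    BRANCH_SITES,
    INLET_SITE,
    OUTLET_SITES,
    Phase,
    Site,
    VelocityWaveform,
    write_waveform,
    read_waveform,
)

__all__ = [
    "WaveformParams",
    "SyntheticPatient",
    "gen_waveform",
    "gen_patient",
    "write_patient",
    "read_patient",
    "PRE_REPAIR_PEAK_VELOCITIES",
    "PRE_REPAIR_DIAMETERS_MM",
    "POST_REPAIR_PEAK_VELOCITIES",
    "POST_REPAIR_DIAMETERS_MM",
]

# Clinically plausible defaults (m/s and mm) for a paediatric coarctation.
PRE_REPAIR_PEAK_VELOCITIES: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 1.3,
    Site.INNOMINATE: 1.11,
    Site.LCCA: 0.81,
    Site.LSCA: 0.70,
    Site.COARCTATION: 3.49,
    Site.DESCENDING_AORTA: 0.63,
}
PRE_REPAIR_DIAMETERS_MM: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 13.00,
    Site.INNOMINATE: 8.15,
    Site.LCCA: 4.30,
    Site.LSCA: 5.00,
    Site.COARCTATION: 3.37,
    Site.DESCENDING_AORTA: 8.29,
}
POST_REPAIR_PEAK_VELOCITIES: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 1.3,
    Site.INNOMINATE: 0.84,
    Site.COARCTATION: 2.38,
}
POST_REPAIR_DIAMETERS_MM: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 11.21,
    Site.INNOMINATE: 6.98,
    Site.COARCTATION: 6.00,
}
#: Healthy-state patch diameters used for the hypothetical case.
HEALTHY_DIAMETERS_MM: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 11.21,
    Site.INNOMINATE: 8.15,
    Site.LCCA: 4.30,
    Site.LSCA: 5.00,
    Site.DESCENDING_AORTA: 8.29,
}

#: Per-site phase lag as a fraction of the cardiac period (pulse transit).
_PHASE_LAG_FRACTION: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 0.0,
    Site.COARCTATION: 0.01,
    Site.INNOMINATE: 0.02,
    Site.LCCA: 0.03,
    Site.LSCA: 0.04,
    Site.DESCENDING_AORTA: 0.08,
}
#: Diastolic tail amplitude fraction per site (large through a tight
#: stenosis, small elsewhere).
_TAIL_FRACTION: Dict[Site, float] = {
    Site.ASCENDING_AORTA: 0.05,
    Site.INNOMINATE: 0.05,
    Site.LCCA: 0.05,
    Site.LSCA: 0.05,
    Site.COARCTATION: 0.25,
    Site.DESCENDING_AORTA: 0.10,
}


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of one synthetic Doppler envelope.

    ``systolic_fraction`` is the fraction of the cycle occupied by the
    systolic pulse; ``diastolic_tail_fraction`` the tail amplitude at its
    onset as a fraction of the peak (the tail decays with a time constant
    of one period); ``phase_lag`` a cyclic shift in seconds; ``noise_sd``
    the additive Gaussian noise level in m/s.
    """

    peak_velocity: float
    heart_rate_bpm: float = 120.0
    systolic_fraction: float = 0.35
    diastolic_tail_fraction: float = 0.0
    phase_lag: float = 0.0
    noise_sd: float = 0.0
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_velocity <= 0:
            raise InvalidParameterError("peak_velocity must be positive")
        if not (0.0 < self.systolic_fraction < 1.0):
            raise InvalidParameterError("systolic_fraction must be in (0, 1)")
        if not (0.0 <= self.diastolic_tail_fraction < 1.0):
            raise InvalidParameterError("diastolic_tail_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.n_samples < 3:
            raise InvalidParameterError("n_samples must be at least 3")
        if self.heart_rate_bpm <= 0:
            raise InvalidParameterError("heart_rate_bpm must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate_bpm


def _envelope(tau: np.ndarray, p: WaveformParams) -> np.ndarray:
    """Noise-free envelope on cycle-local times ``tau`` in [0, period]."""
    T = p.period
    t_sys = p.systolic_fraction * T
    t_peak = 0.5 * t_sys
    sys_pulse = np.where(
        tau <= t_sys,
        0.5 * p.peak_velocity * (1.0 - np.cos(2.0 * np.pi * tau / t_sys)),
        0.0,
    )
    tail = np.where(
        tau >= t_peak,
        p.diastolic_tail_fraction
        * p.peak_velocity
        * np.exp(-(tau - t_peak) / T),
        0.0,
    )
    return np.maximum(sys_pulse, tail)


def gen_waveform(
    p: WaveformParams,
    site: Site = Site.ASCENDING_AORTA,
    phase: Optional[Phase] = None,
) -> VelocityWaveform:
    """Generate one synthetic envelope waveform.

    The sampled pulse is renormalised so its maximum equals
    ``peak_velocity`` exactly (before noise), independent of where the
    analytic peak falls relative to the grid.  Same seed → identical
    samples.
    """
    T = p.period
    t = np.linspace(0.0, T, p.n_samples)
    shifted = t - p.phase_lag
    tau = np.mod(shifted, T)
    # keep end-diastole at tau=T rather than wrapping to the systolic onset
    wrap = (tau == 0.0) & (shifted > 0.0)
    tau[wrap] = T
    v = _envelope(tau, p)
    vmax = float(np.max(v))
    if vmax > 0:
        # divide first so the sampled maximum equals peak_velocity exactly
        v = v / vmax * p.peak_velocity
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        v = v + rng.normal(0.0, p.noise_sd, size=v.shape)
        np.clip(v, 0.0, None, out=v)
    return VelocityWaveform(
        site=site, t=t, v=v, heart_rate_bpm=p.heart_rate_bpm, phase=phase
    )


@dataclass
class SyntheticPatient:
    """A generated examination with its construction ground truth."""

    scenario: CaseMode
    seed: int
    noise_sd: float
    waveforms: Dict[Site, VelocityWaveform]
    diameters_mm: Dict[Site, float]
    factors: SplitFactors

    @property
    def sites(self) -> list[Site]:
        return list(self.waveforms)


def _add_noise(
    w: VelocityWaveform, noise_sd: float, rng: np.random.Generator
) -> VelocityWaveform:
    if noise_sd <= 0:
        return w
    v = w.v + rng.normal(0.0, noise_sd, size=w.v.shape)
    np.clip(v, 0.0, None, out=v)
    return VelocityWaveform(
        site=w.site, t=w.t, v=v, heart_rate_bpm=w.heart_rate_bpm, phase=w.phase
    )


def _scale_velocity(w: VelocityWaveform, factor: float) -> VelocityWaveform:
    return VelocityWaveform(
        site=w.site,
        t=w.t,
        v=w.v * factor,
        heart_rate_bpm=w.heart_rate_bpm,
        phase=w.phase,
    )


def gen_patient(
    scenario: CaseMode,
    seed: int,
    noise_sd: float = 0.0,
    target_outlet_scale: float = 0.8243,
    target_descending_scale: float = 0.5101,
    descending_fraction: float = 0.70,
    n_samples: int = 100,
) -> SyntheticPatient:
    """Generate a full synthetic examination for one data regime.

    ``full_data`` yields all six sites; ``partial_post_repair`` only the
    ascending aorta, innominate and coarctation (the three measurements a
    restless post-repair examination yielded); ``hypothetical_healthy``
    only the ascending aorta plus healthy patch diameters.

    The patient is *constructed* so that the processing pipeline (default
    smoothing window and period, conversion to flow, mass-conservation
    scaling) recovers exactly ``target_outlet_scale`` (full data) or
    ``target_descending_scale`` (partial data) on the noise-free
    waveforms; the targets are stored as ground truth in ``factors``.
    Noise, when requested, is added after this calibration.
    """
    from .pipeline import DEFAULT_SMOOTH_WINDOW, processed_flow  # lazy: avoid cycle

    scenario = CaseMode(scenario)
    rng = np.random.default_rng(seed)
    base_hr = float(rng.uniform(95.0, 130.0))

    def site_waveform(
        site: Site, amp: float, phase: Phase, lag_frac: Optional[float] = None
    ) -> VelocityWaveform:
        hr = base_hr + float(rng.uniform(-5.0, 5.0))
        lag = (_PHASE_LAG_FRACTION[site] if lag_frac is None else lag_frac) * (
            60.0 / hr
        )
        params = WaveformParams(
            peak_velocity=amp,
            heart_rate_bpm=hr,
            diastolic_tail_fraction=_TAIL_FRACTION[site],
            phase_lag=lag,
            noise_sd=0.0,
            n_samples=n_samples,
        )
        return gen_waveform(params, site=site, phase=phase)

    if scenario is CaseMode.FULL_DATA:
        waveforms = {
            site: site_waveform(site, amp, Phase.PRE_REPAIR)
            for site, amp in PRE_REPAIR_PEAK_VELOCITIES.items()
        }
        diameters = dict(PRE_REPAIR_DIAMETERS_MM)
        # calibrate: scale outlet velocities so the pipeline's uniform
        # mass-conservation factor equals the target exactly
        inlet_flow = processed_flow(
            waveforms[INLET_SITE], diameters[INLET_SITE], inlet=True
        )
        outlet_flows = [
            processed_flow(waveforms[s], diameters[s], inlet=False)
            for s in OUTLET_SITES
        ]
        _, raw_factor = conserve_mass_scale(inlet_flow, outlet_flows)
        alpha = raw_factor / target_outlet_scale
        for s in OUTLET_SITES:
            waveforms[s] = _scale_velocity(waveforms[s], alpha)
        calibrated = [
            processed_flow(waveforms[s], diameters[s], inlet=False)
            for s in OUTLET_SITES
        ]
        factors = SplitFactors(
            outlet_scale=target_outlet_scale,
            descending_fraction=descending_fraction,
            branch_ratios=branch_ratios_from(calibrated),
        )
    elif scenario is CaseMode.PARTIAL_POST_REPAIR:
        ratios = {Site.LCCA: 1.09 / 3.72, Site.LSCA: 1.09 / 3.72}
        waveforms = {
            site: site_waveform(site, amp, Phase.POST_REPAIR, lag_frac=0.0)
            for site, amp in POST_REPAIR_PEAK_VELOCITIES.items()
        }
        diameters = dict(POST_REPAIR_DIAMETERS_MM)
        # calibrate the innominate amplitude so the solved descending
        # factor equals the target exactly (bisection on the amplitude)
        from .flow_split import derive_case2_outlets
        from scipy.optimize import bisect as _bisect

        case1 = SplitFactors(
            outlet_scale=target_outlet_scale, branch_ratios=ratios
        )
        inlet_flow = processed_flow(
            waveforms[INLET_SITE], diameters[INLET_SITE], inlet=True
        )

        from .errors import DegenerateInputError

        def solved_s(amp_scale: float) -> float:
            inn = _scale_velocity(waveforms[Site.INNOMINATE], amp_scale)
            inn_flow = processed_flow(inn, diameters[Site.INNOMINATE], inlet=False)
            try:
                _, f = derive_case2_outlets(case1, inlet_flow, inn_flow)
            except DegenerateInputError:
                return 0.0  # branches alone already exceed the inlet peak
            return f.descending_inlet_scale

        target = target_descending_scale
        amp = _bisect(
            lambda a: solved_s(a) - target, 1e-3, 50.0, xtol=1e-12
        )
        waveforms[Site.INNOMINATE] = _scale_velocity(
            waveforms[Site.INNOMINATE], float(amp)
        )
        factors = SplitFactors(
            outlet_scale=target_outlet_scale,
            descending_inlet_scale=target_descending_scale,
            descending_fraction=descending_fraction,
            branch_ratios=ratios,
        )
    elif scenario is CaseMode.HYPOTHETICAL_HEALTHY:
        waveforms = {
            INLET_SITE: site_waveform(
                INLET_SITE,
                POST_REPAIR_PEAK_VELOCITIES[INLET_SITE],
                Phase.POST_REPAIR,
            )
        }
        diameters = dict(HEALTHY_DIAMETERS_MM)
        factors = SplitFactors(descending_fraction=descending_fraction)
    else:  # pragma: no cover
        raise InvalidParameterError(f"unknown scenario {scenario}")

    if noise_sd > 0:
        waveforms = {
            s: _add_noise(w, noise_sd, rng) for s, w in waveforms.items()
        }
    return SyntheticPatient(
        scenario=scenario,
        seed=seed,
        noise_sd=noise_sd,
        waveforms=waveforms,
        diameters_mm=diameters,
        factors=factors,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_patient(patient: SyntheticPatient, directory: Union[str, Path]) -> Path:
    """Write waveform text files plus a ``manifest.yaml`` carrying the
    diameters and ground-truth factors; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for site, w in patient.waveforms.items():
        write_waveform(w, directory / f"{site.value}.txt")
    manifest = {
        "scenario": patient.scenario.value,
        "seed": patient.seed,
        "noise_sd": patient.noise_sd,
        "waveform_files": {
            s.value: f"{s.value}.txt" for s in patient.waveforms
        },
        "diameters_mm": {s.value: d for s, d in patient.diameters_mm.items()},
        "ground_truth": {
            "outlet_scale": patient.factors.outlet_scale,
            "descending_inlet_scale": patient.factors.descending_inlet_scale,
            "descending_fraction": patient.factors.descending_fraction,
            "branch_ratios": {
                Site(s).value: r for s, r in patient.factors.branch_ratios.items()
            },
        },
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_patient(directory: Union[str, Path]) -> SyntheticPatient:
    """Load a patient previously written by :func:`write_patient`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    waveforms = {
        Site(s): read_waveform(directory / fname)
        for s, fname in manifest["waveform_files"].items()
    }
    gt = manifest["ground_truth"]
    factors = SplitFactors(
        outlet_scale=gt["outlet_scale"],
        descending_inlet_scale=gt["descending_inlet_scale"],
        descending_fraction=gt["descending_fraction"],
        branch_ratios={Site(s): r for s, r in gt["branch_ratios"].items()},
    )
    return SyntheticPatient(
        scenario=CaseMode(manifest["scenario"]),
        seed=int(manifest["seed"]),
        noise_sd=float(manifest["noise_sd"]),
        waveforms=waveforms,
        diameters_mm={
            Site(s): float(d) for s, d in manifest["diameters_mm"].items()
        },
        factors=factors,
    )
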