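"""Mass-consistent outlet flow derivation for three data regimes.

Doppler envelopes overestimate average velocity, so outlet flow waveforms
built from them violate mass conservation against the inlet.  Depending on
how much data an examination yielded, one of three regimes applies:

``full_data`` (pre-repair, every site measured)
    All outlet waveforms are scaled by one uniform factor so that the peak
    of their sum matches the peak inlet flow
    (:func:`conserve_mass_scale`).

``partial_post_repair`` (only inlet and innominate measured)
    The innominate keeps the uniform factor found pre-repair; the carotid
    and subclavian are imputed from the pre-repair branch-to-innominate
    peak ratios; the descending aorta is given the inlet waveform scaled by
    a factor solved so the summed outlet peak matches the inlet peak
    (:func:`derive_case2_outlets`).

``hypothetical_healthy`` (no data; idealised post-repair state)
    A fixed fraction of the inlet flow (default 70%, the healthy-aorta
    value reported in the literature) exits the descending aorta and the
    remainder is divided among the branches by area ratio
    (:func:`derive_case3_outlets`).

Finally, steady peak-systolic boundary values are extracted at the instant
of maximum inlet flow (:func:`extract_steady_bcs`); the resulting
:class:`BoundarySpec` enforces inlet = Σ outlets exactly, which is the mass
conservation contract the CFD case is written from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from scipy.optimize import bisect

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidParameterError,
)
from .hemodynamics import FlowWaveform, FluidProperties
from .waveforms import BRANCH_SITES, Site

__all__ = [
    "CaseMode",
    "SplitFactors",
    "BoundarySpec",
    "conserve_mass_scale",
    "derive_case2_outlets",
    "derive_case3_outlets",
    "extract_steady_bcs",
    "branch_ratios_from",
    "boundary_report",
    "write_boundary_report",
]

#: Number of points of the common uniform grid used when summing waveforms.
SUM_GRID_N = 1000

#: Relative tolerance of the mass-conservation contract.
MASS_TOL = 1e-9


class CaseMode(str, Enum):
    """Data regime of an examination."""

    FULL_DATA = "full_data"
    PARTIAL_POST_REPAIR = "partial_post_repair"
    HYPOTHETICAL_HEALTHY = "hypothetical_healthy"


def _check_factor(name: str, value: Optional[float], lo: float, hi: float) -> None:
    if value is not None and not (lo < value <= hi):
        raise InvalidParameterError(f"{name}={value} outside ({lo}, {hi}]")


@dataclass
class SplitFactors:
    """Scaling factors that tie the three regimes together.

    ``outlet_scale`` is the uniform full-data factor; ``branch_ratios`` are
    the full-data branch-to-innominate peak-flow ratios reused post-repair;
    ``descending_inlet_scale`` is the solved post-repair descending factor;
    ``descending_fraction`` is the healthy-case descending flow fraction.
    """

    outlet_scale: Optional[float] = None
    descending_inlet_scale: Optional[float] = None
    descending_fraction: float = 0.70
    branch_ratios: Dict[Site, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_factor("outlet_scale", self.outlet_scale, 0.0, 2.0)
        _check_factor("descending_inlet_scale", self.descending_inlet_scale, 0.0, 2.0)
        if not (0.0 < self.descending_fraction < 1.0):
            raise InvalidParameterError(
                f"descending_fraction={self.descending_fraction} outside (0, 1)"
            )
        for site, r in self.branch_ratios.items():
            _check_factor(f"branch_ratio[{Site(site).value}]", r, 0.0, 2.0)


@dataclass(frozen=True)
class BoundarySpec:
    """Steady peak-systolic volumetric flow rates, ready for case writing.

    The inlet value must equal the sum of the outlet values to relative
    tolerance 1e-9 — by construction it is the sum, so the CFD problem is
    exactly mass-conservative regardless of how the raw measurements
    disagreed.
    """

    outlet_flows: Dict[Site, float]
    inlet_flow: float
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if not self.outlet_flows:
            raise ConfigurationError("at least one outlet is required")
        total = float(sum(self.outlet_flows.values()))
        if total <= 0:
            raise DegenerateInputError("outlet flows sum to zero")
        if abs(self.inlet_flow - total) > MASS_TOL * total:
            raise InvalidParameterError(
                f"inlet flow {self.inlet_flow} != sum of outlets {total} "
                f"(mass-conservation contract)"
            )


def _common_grid(
    waveforms: Sequence[FlowWaveform], n: int = SUM_GRID_N
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform grid over the shared span and the pointwise sum on it.

    All waveforms must share start and end times (normalise periods first).
    """
    t0 = waveforms[0].t[0]
    t1 = waveforms[0].t[-1]
    span = t1 - t0
    if span <= 0:
        raise DegenerateInputError("waveforms have zero span")
    for w in waveforms:
        if abs(w.t[0] - t0) > 1e-9 * span or abs(w.t[-1] - t1) > 1e-9 * span:
            raise InvalidParameterError(
                "waveforms must share a common normalised period before summing"
            )
    grid = np.linspace(t0, t1, n)
    total = np.zeros(n)
    for w in waveforms:
        total += np.interp(grid, w.t, w.q)
    return grid, total


def conserve_mass_scale(
    inlet: FlowWaveform,
    outlets: Sequence[FlowWaveform],
    *,
    align_peaks: bool = False,
    grid_n: int = SUM_GRID_N,
) -> Tuple[List[FlowWaveform], float]:
    """Uniformly scale all outlets so the peak of their sum matches the
    peak inlet flow.

    Returns ``(scaled_outlets, factor)`` where
    ``factor = peak(inlet) / peak(Σ outlets)``, the sum being evaluated on a
    common uniform grid of ``grid_n`` points.

    ``align_peaks=True`` enables an alternative strategy for comparison
    studies: every outlet except the descending aorta is cyclically shifted
    so that its peak coincides with the inlet peak before scaling.  It is
    off by default.
    """
    if not outlets:
        raise ConfigurationError("at least one outlet is required")
    outlets = list(outlets)
    if align_peaks:
        t_peak_in, _ = inlet.peak()
        outlets = [
            _cyclic_shift_to(o, t_peak_in)
            if o.patch is not Site.DESCENDING_AORTA
            else o
            for o in outlets
        ]
    grid, total = _common_grid([*outlets, inlet], grid_n)
    inlet_on_grid = np.interp(grid, inlet.t, inlet.q)
    total -= inlet_on_grid  # _common_grid summed the inlet too
    peak_sum = float(np.max(total))
    if peak_sum <= 0:
        raise DegenerateInputError("summed outlet flow has zero peak")
    # both peaks evaluated on the same resampled grid for self-consistency
    peak_in = float(np.max(inlet_on_grid))
    factor = peak_in / peak_sum
    return [o.scaled(factor) for o in outlets], factor


def _cyclic_shift_to(w: FlowWaveform, t_target: float) -> FlowWaveform:
    """Cyclically shift a one-cycle waveform so its peak sits at
    ``t_target`` (used by the optional peak-alignment strategy)."""
    t_peak, _ = w.peak()
    span = w.period
    shift = (t_target - t_peak) % span
    # evaluate the periodic extension at t - shift
    rel = (w.t - w.t[0] - shift) % span
    q = np.interp(rel, w.t - w.t[0], w.q)
    return FlowWaveform(patch=w.patch, t=w.t.copy(), q=q)


def branch_ratios_from(case1_outlets: Sequence[FlowWaveform]) -> Dict[Site, float]:
    """Peak-flow ratios of the carotid and subclavian relative to the
    innominate, taken from a full-data outlet set."""
    by_site = {w.patch: w for w in case1_outlets}
    if Site.INNOMINATE not in by_site:
        raise ConfigurationError("innominate waveform is required")
    _, q_inn = by_site[Site.INNOMINATE].peak()
    if q_inn <= 0:
        raise DegenerateInputError("innominate peak flow is zero")
    ratios: Dict[Site, float] = {}
    for site in (Site.LCCA, Site.LSCA):
        if site in by_site:
            _, q = by_site[site].peak()
            ratios[site] = q / q_inn
    return ratios


def derive_case2_outlets(
    case1_factors: SplitFactors,
    inlet2: FlowWaveform,
    innominate2: FlowWaveform,
    *,
    grid_n: int = SUM_GRID_N,
    solver_xtol: float = 1e-10,
) -> Tuple[List[FlowWaveform], SplitFactors]:
    """Impute the post-repair outlet set from inlet + innominate alone.

    The innominate is scaled by the full-data ``outlet_scale``; the carotid
    and subclavian are synthesised as ``branch_ratio × scaled innominate``;
    the descending aorta is the inlet waveform times a factor ``s`` solved
    (by bisection, since the peak of the sum is monotone but not linear in
    ``s`` when phases differ) so that the summed outlet peak equals the
    inlet peak.  Returns the four outlets and factors carrying ``s`` as
    ``descending_inlet_scale``.
    """
    if case1_factors.outlet_scale is None:
        raise ConfigurationError("case1_factors.outlet_scale is required")
    missing = [
        s.value for s in (Site.LCCA, Site.LSCA)
        if s not in case1_factors.branch_ratios
    ]
    if missing:
        raise ConfigurationError(f"missing branch ratios for: {', '.join(missing)}")

    inn = innominate2.scaled(case1_factors.outlet_scale)
    lcca = inn.scaled(case1_factors.branch_ratios[Site.LCCA], patch=Site.LCCA)
    lsca = inn.scaled(case1_factors.branch_ratios[Site.LSCA], patch=Site.LSCA)
    grid, branch_sum = _common_grid([inn, lcca, lsca, inlet2], grid_n)
    inlet_on_grid = np.interp(grid, inlet2.t, inlet2.q)
    branch_only = branch_sum - inlet_on_grid  # _common_grid summed inlet2 too
    peak_in = float(np.max(inlet_on_grid))
    if peak_in <= 0:
        raise DegenerateInputError("inlet peak flow is zero")

    def residual(s: float) -> float:
        return float(np.max(branch_only + s * inlet_on_grid)) - peak_in

    lo, hi = 1e-12, 2.0
    if residual(lo) > 0 or residual(hi) < 0:
        raise DegenerateInputError(
            "no descending scale in (0, 2] balances the outlet peak sum"
        )
    s = float(bisect(residual, lo, hi, xtol=solver_xtol))
    desc = inlet2.scaled(s, patch=Site.DESCENDING_AORTA)
    factors = SplitFactors(
        outlet_scale=case1_factors.outlet_scale,
        descending_inlet_scale=s,
        descending_fraction=case1_factors.descending_fraction,
        branch_ratios=dict(case1_factors.branch_ratios),
    )
    return [inn, lcca, lsca, desc], factors


def derive_case3_outlets(
    inlet: FlowWaveform,
    patch_areas: Mapping[Site, float],
    fraction: float = 0.70,
) -> List[FlowWaveform]:
    """Healthy-state split: a fixed fraction of the inlet flow leaves by the
    descending aorta, the rest divides among the branches by area ratio.

    The outlets sum to the inlet waveform pointwise by construction, and the
    split is invariant under uniform rescaling of all branch areas.
    """
    if not (0.0 < fraction < 1.0):
        raise InvalidParameterError(f"fraction={fraction} outside (0, 1)")
    missing = [s.value for s in BRANCH_SITES if s not in patch_areas]
    if missing:
        raise ConfigurationError(f"missing patch areas for: {', '.join(missing)}")
    area_sum = float(sum(patch_areas[s] for s in BRANCH_SITES))
    if area_sum <= 0:
        raise DegenerateInputError("branch areas sum to zero")
    outlets = [inlet.scaled(fraction, patch=Site.DESCENDING_AORTA)]
    for site in BRANCH_SITES:
        share = (1.0 - fraction) * patch_areas[site] / area_sum
        outlets.append(inlet.scaled(share, patch=site))
    return outlets


def extract_steady_bcs(
    inlet: FlowWaveform,
    outlets: Sequence[FlowWaveform],
    fluid: FluidProperties = FluidProperties(),
) -> BoundarySpec:
    """Extract steady peak-systolic boundary values.

    ``t*`` is the first time of the inlet flow maximum; each outlet's steady
    value is its flow at ``t*`` (linear interpolation).  The inlet value of
    the returned :class:`BoundarySpec` is the *sum* of the outlet values —
    not the raw inlet peak — so the written case is exactly
    mass-conservative.
    """
    if not outlets:
        raise ConfigurationError("at least one outlet is required")
    t_star, _ = inlet.peak()
    outlet_flows = {o.patch: o.at(t_star) for o in outlets}
    return BoundarySpec(
        outlet_flows=outlet_flows,
        inlet_flow=float(sum(outlet_flows.values())),
        fluid=fluid,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def boundary_report(
    spec: BoundarySpec, factors: Optional[SplitFactors] = None
) -> dict:
    """Serialisable summary of steady boundary values.

    Human-readable values are in 1e-5 m³/s (the customary table scale);
    machine fields stay in SI.
    """
    order = [s for s in Site if s in spec.outlet_flows]
    report = {
        "units_readable": "1e-5 m^3/s",
        "inlet": {
            "value_readable": round(spec.inlet_flow * 1e5, 4),
            "value_si": spec.inlet_flow,
        },
        "outlets": {
            s.value: {
                "value_readable": round(spec.outlet_flows[s] * 1e5, 4),
                "value_si": spec.outlet_flows[s],
            }
            for s in order
        },
        "fluid": {
            "kinematic_viscosity_m2_s": spec.fluid.kinematic_viscosity,
            "density_kg_m3": spec.fluid.density,
        },
    }
    if factors is not None:
        report["factors"] = {
            "outlet_scale": factors.outlet_scale,
            "descending_inlet_scale": factors.descending_inlet_scale,
            "descending_fraction": factors.descending_fraction,
            "branch_ratios": {
                Site(s).value: r for s, r in factors.branch_ratios.items()
            },
        }
    return report


def write_boundary_report(
    spec: BoundarySpec,
    path: Union[str, Path],
    factors: Optional[SplitFactors] = None,
) -> None:
    """Write :func:`boundary_report` as YAML (or JSON if the suffix is
    ``.json``)."""
    path = Path(path)
    report = boundary_report(spec, factors)
    if path.suffix == ".json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(report, sort_keys=True))
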