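"""Scalar hemodynamic formulas and velocity→flow conversion.

The clinical estimate of the pressure drop across a stenosis from a Doppler
peak velocity is the simplified Bernoulli relation ΔP = 4 v², with ΔP in
mmHg and v in m/s.  The coefficient 4 is the rounded value of
½ ρ · (Pa→mmHg) for blood: ½ · 1060 · 0.00750062 = 3.9753, i.e. the relation
neglects frictional losses and the proximal velocity and folds the unit
conversion into a single round number.

Volumetric flow at a vessel patch is obtained from the envelope velocity as
Q(t) = A · v_ave(t).  A Doppler envelope records the *maximum* velocity in
the sample volume, so an assumption about the cross-sectional profile is
needed: at outlets the average is taken equal to the maximum
(:attr:`VelocityProfile.MAX_EQUALS_AVG`); at the inlet a parabolic profile
is assumed, where the average is half the maximum
(:attr:`VelocityProfile.PARABOLIC_HALF_MAX`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidParameterError
from .waveforms import Site, VelocityWaveform

__all__ = [
    "PA_TO_MMHG",
    "FluidProperties",
    "FlowWaveform",
    "VelocityProfile",
    "bernoulli_pressure_mmHg",
    "velocity_to_flow",
    "circular_area",
    "kinematic_pressure_to_mmHg",
    "relative_difference_pct",
]

#: Pascal → mmHg conversion factor, pinned to 6 significant figures for
#: bit-stable output.
PA_TO_MMHG = 0.00750062


@dataclass(frozen=True)
class FluidProperties:
    """Blood modelled as an incompressible Newtonian fluid.

    Defaults are the standard values for blood used throughout the package:
    kinematic viscosity ν = 3.78e-6 m²/s and density ρ = 1060 kg/m³.
    """

    kinematic_viscosity: float = 3.78e-6
    density: float = 1060.0

    def __post_init__(self) -> None:
        if self.kinematic_viscosity <= 0 or self.density <= 0:
            raise InvalidParameterError("fluid properties must be strictly positive")


@dataclass(frozen=True)
class FlowWaveform:
    """Volumetric flow rate versus time at a named boundary patch.

    ``t`` in seconds (strictly increasing, one cardiac cycle), ``q`` in m³/s
    (non-negative).
    """

    patch: Site
    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        if t.ndim != 1 or q.ndim != 1 or t.shape != q.shape:
            raise InvalidParameterError("t and q must be 1-D arrays of equal length")
        if t.size < 3:
            raise InvalidParameterError("a flow waveform needs at least 3 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("sample times must be strictly increasing")
        if np.any(q < -1e-30):
            raise InvalidParameterError("flow rates must be non-negative")

    @property
    def period(self) -> float:
        return float(self.t[-1] - self.t[0])

    def peak(self) -> tuple[float, float]:
        """``(t_peak, q_max)`` with ties broken to the earliest sample."""
        i = int(np.argmax(self.q))
        return float(self.t[i]), float(self.q[i])

    def scaled(self, factor: float, patch: Optional[Site] = None) -> "FlowWaveform":
        """A copy with flow values multiplied by ``factor`` (and optionally
        relabelled to another patch)."""
        return FlowWaveform(
            patch=patch if patch is not None else self.patch,
            t=self.t.copy(),
            q=self.q * factor,
        )

    def at(self, time: float) -> float:
        """Flow rate at ``time`` by linear interpolation."""
        return float(np.interp(time, self.t, self.q))


class VelocityProfile(str, Enum):
    """Cross-sectional profile assumption relating envelope to average
    velocity."""

    MAX_EQUALS_AVG = "max_equals_avg"
    PARABOLIC_HALF_MAX = "parabolic_half_max"


def bernoulli_pressure_mmHg(v_max: float) -> float:
    """Simplified Bernoulli pressure difference ΔP = 4 v², in mmHg.

    ``v_max`` is the peak Doppler velocity in m/s.
    """
    if v_max < 0:
        raise InvalidParameterError("velocity must be non-negative")
    return 4.0 * v_max * v_max


def velocity_to_flow(
    w: VelocityWaveform,
    area: float,
    profile: VelocityProfile = VelocityProfile.MAX_EQUALS_AVG,
) -> FlowWaveform:
    """Convert an envelope velocity waveform to volumetric flow, Q = A·v_ave.

    ``area`` is the patch cross-sectional area in m².  Under
    ``MAX_EQUALS_AVG`` the envelope is used directly (v_ave = v); under
    ``PARABOLIC_HALF_MAX`` the average is half the envelope (v_ave = v/2).
    The time grid is preserved.
    """
    if area <= 0:
        raise InvalidParameterError("area must be positive")
    profile = VelocityProfile(profile)
    factor = 0.5 if profile is VelocityProfile.PARABOLIC_HALF_MAX else 1.0
    return FlowWaveform(patch=w.site, t=w.t.copy(), q=area * factor * w.v)


def circular_area(d_mm: float) -> float:
    """Area in m² of a circular cross-section of diameter ``d_mm`` (mm)."""
    if d_mm <= 0:
        raise InvalidParameterError("diameter must be positive")
    r_m = d_mm / 2000.0
    return float(np.pi) * r_m * r_m


def kinematic_pressure_to_mmHg(p_kin: float, fluid: FluidProperties) -> float:
    """Convert solver kinematic pressure (m²/s²) to clinical mmHg.

    Incompressible finite-volume solvers report p/ρ; multiplying by the
    density and the Pa→mmHg factor recovers clinical units.
    """
    return p_kin * fluid.density * PA_TO_MMHG


def relative_difference_pct(reference: float, other: float) -> float:
    """Signed relative difference ``(reference - other) / reference`` in
    percent; positive when ``other`` underestimates the reference.

    Used e.g. to compare a CFD peak stenosis velocity against the Doppler
    measurement it should reproduce.
    """
    if reference == 0:
        raise InvalidParameterError("reference value must be nonzero")
    return (reference - other) / reference * 100.0
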