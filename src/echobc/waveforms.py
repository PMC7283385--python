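"""Doppler velocity waveforms: representation, cleaning, normalisation.

A transthoracic Doppler examination of an aortic coarctation patient yields,
per measurement site, the envelope (maximum) velocity over the cardiac cycle.
This module represents one digitised cycle as a :class:`VelocityWaveform`
and provides the operations the boundary-condition pipeline needs:

* local-quadratic smoothing of digitisation noise (:func:`smooth_waveform`),
* rescaling the cycle to a common period so measurements taken at different
  heart rates are comparable (:func:`normalize_period`); the conventional
  reference is 0.5 s, i.e. 120 beats per minute,
* peak extraction (:func:`peak_of`) and resampling onto a uniform grid
  (:func:`resample_uniform`).

Waveforms are read and written as plain two-column delimited text with
``#``-prefixed metadata lines, so they can be produced by any digitisation
tool or spreadsheet.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np

from .errors import DegenerateWaveformError, InvalidParameterError, ParseError

__all__ = [
    "Site",
    "Phase",
    "VelocityWaveform",
    "INLET_SITE",
    "BRANCH_SITES",
    "OUTLET_SITES",
    "DEFAULT_PERIOD_S",
    "smooth_waveform",
    "normalize_period",
    "peak_of",
    "resample_uniform",
    "read_waveform",
    "write_waveform",
]

#: Reference cardiac period all waveforms are normalised to (120 BPM).
DEFAULT_PERIOD_S = 0.5


class Site(str, Enum):
    """Doppler measurement sites around the aortic arch."""

    ASCENDING_AORTA = "ascending_aorta"
    INNOMINATE = "innominate"
    LCCA = "lcca"
    LSCA = "lsca"
    COARCTATION = "coarctation"
    DESCENDING_AORTA = "descending_aorta"


#: The unique inlet site of the computational domain (aortic sinus level).
INLET_SITE = Site.ASCENDING_AORTA

#: Supra-aortic branch vessels, in anatomical order.
BRANCH_SITES = (Site.INNOMINATE, Site.LCCA, Site.LSCA)

#: All outlet patches of the arch model.
OUTLET_SITES = BRANCH_SITES + (Site.DESCENDING_AORTA,)


class Phase(str, Enum):
    """Examination phase relative to the surgical repair."""

    PRE_REPAIR = "pre_repair"
    POST_REPAIR = "post_repair"


@dataclass(frozen=True)
class VelocityWaveform:
    """One cardiac cycle of Doppler envelope velocity at a named site.

    Parameters
    ----------
    site:
        Measurement location.
    t:
        Sample times in seconds, strictly increasing, spanning exactly one
        cardiac cycle (``t[-1] - t[0]`` is the period).
    v:
        Envelope velocity magnitudes in m/s, non-negative.
    heart_rate_bpm:
        Heart rate from ECG monitoring at acquisition time, if available.
    phase:
        Pre- or post-repair examination.
    """

    site: Site
    t: np.ndarray
    v: np.ndarray
    heart_rate_bpm: Optional[float] = None
    phase: Optional[Phase] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise InvalidParameterError("t and v must be 1-D arrays of equal length")
        if t.size < 3:
            raise InvalidParameterError("a waveform needs at least 3 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("sample times must be strictly increasing")
        if np.any(v < 0):
            raise InvalidParameterError("envelope velocities must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def period(self) -> float:
        """Cycle length in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def equivalent_heart_rate_bpm(self) -> float:
        """Heart rate implied by the waveform's own period."""
        return 60.0 / self.period


def _local_quadratic(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Centred least-squares quadratic fit, shrunken windows at the ends."""
    n = y.size
    half = window // 2
    out = np.empty_like(y)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        if k == 0:
            out[i] = y[i]
            continue
        sl = slice(i - k, i + k + 1)
        # centre the abscissa for conditioning; degree 2 (or 1 on 2 points,
        # unreachable since windows are odd)
        x = t[sl] - t[i]
        coeffs = np.polynomial.polynomial.polyfit(x, y[sl], deg=min(2, 2 * k))
        out[i] = coeffs[0]
    return out


def smooth_waveform(w: VelocityWaveform, window: int = 7) -> VelocityWaveform:
    """Smooth digitisation noise with a centred local quadratic fit.

    Each sample is replaced by the value at its own time of a least-squares
    parabola fitted over ``window`` neighbouring samples; near the ends the
    window shrinks symmetrically.  A quadratic fit preserves the amplitude
    of a smooth systolic peak far better than a moving average.  Velocities
    are clamped at zero afterwards (Doppler envelopes are magnitudes).

    ``window`` must be odd and within ``[1, n_samples]``; ``window=1`` is the
    identity.
    """
    n = w.n_samples
    if window % 2 == 0 or not 1 <= window <= n:
        raise InvalidParameterError(
            f"window must be odd and in [1, {n}], got {window}"
        )
    if window == 1:
        return w
    v = _local_quadratic(w.t, w.v, window)
    np.clip(v, 0.0, None, out=v)
    return replace(w, v=v)


def normalize_period(
    w: VelocityWaveform, target_period: float = DEFAULT_PERIOD_S
) -> VelocityWaveform:
    """Linearly rescale the time axis to a common cardiac period.

    The time axis becomes ``t' = (t - t0) * target_period / period`` so the
    cycle starts at zero and spans exactly ``target_period``; velocities are
    untouched, hence the peak value is invariant.  This does not model the
    physiological change of waveform shape with heart rate — it only makes
    cycles acquired at different rates comparable.  The stored heart rate is
    replaced by the equivalent rate ``60 / target_period``.
    """
    if target_period <= 0:
        raise InvalidParameterError("target_period must be positive")
    span = w.period
    if span <= 0:
        raise DegenerateWaveformError("waveform has zero time span")
    t = (w.t - w.t[0]) * (target_period / span)
    # enforce the exact endpoint despite rounding
    t[-1] = target_period
    return replace(w, t=t, heart_rate_bpm=60.0 / target_period)


def peak_of(w: VelocityWaveform) -> tuple[float, float]:
    """Return ``(t_peak, v_max)``: the sampled maximum velocity and its
    earliest time of occurrence (ties break to the first sample)."""
    i = int(np.argmax(w.v))
    return float(w.t[i]), float(w.v[i])


def resample_uniform(w: VelocityWaveform, n: int) -> VelocityWaveform:
    """Linearly interpolate onto ``n`` equally spaced times over the same
    span; the first and last samples are preserved exactly."""
    if n < 3:
        raise InvalidParameterError("n must be at least 3")
    t = np.linspace(w.t[0], w.t[-1], n)
    v = np.interp(t, w.t, w.v)
    return replace(w, t=t, v=v)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def _parse_metadata(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip().lower()] = val.strip()
    return meta


def read_waveform(source: Union[str, Path, TextIO]) -> VelocityWaveform:
    """Read a waveform from two-column delimited text.

    Expected layout: ``#``-prefixed metadata lines (``site`` required;
    ``phase`` and ``heart_rate_bpm`` optional), an optional column-header
    line, then rows of ``t_s  v_ms`` separated by whitespace or commas.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    meta_lines: list[str] = []
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta_lines.append(line)
            continue
        parts = line.replace(",", " ").split()
        try:
            values = [float(p) for p in parts]
        except ValueError:
            # tolerate a single column-header line
            if not rows and any(c.isalpha() for c in line):
                continue
            raise ParseError(f"line {lineno}: cannot parse {raw!r}")
        if len(values) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(values)}")
        rows.append((values[0], values[1]))
    meta = _parse_metadata(meta_lines)
    if "site" not in meta:
        raise ParseError("missing required '# site:' metadata line")
    try:
        site = Site(meta["site"])
    except ValueError:
        raise ParseError(f"unknown site {meta['site']!r}")
    phase = Phase(meta["phase"]) if "phase" in meta else None
    hr = float(meta["heart_rate_bpm"]) if "heart_rate_bpm" in meta else None
    arr = np.array(rows, dtype=float)
    if arr.size == 0:
        raise ParseError("no data rows found")
    return VelocityWaveform(
        site=site, t=arr[:, 0], v=arr[:, 1], heart_rate_bpm=hr, phase=phase
    )


def write_waveform(w: VelocityWaveform, target: Union[str, Path, TextIO]) -> None:
    """Write a waveform in the same text format :func:`read_waveform` reads.

    Output is deterministic: fixed metadata order, 6 significant digits.
    """
    buf = io.StringIO()
    buf.write(f"# site: {w.site.value}\n")
    if w.phase is not None:
        buf.write(f"# phase: {w.phase.value}\n")
    if w.heart_rate_bpm is not None:
        buf.write(f"# heart_rate_bpm: {w.heart_rate_bpm:.6g}\n")
    buf.write("# columns: t_s v_ms\n")
    for t, v in zip(w.t, w.v):
        buf.write(f"{t:.6g} {v:.6g}\n")
    text = buf.getvalue()
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)
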