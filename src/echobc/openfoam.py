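"""OpenFOAM case emission and sampled-output reading.

Writes the dictionary files a steady incompressible solver needs to run the
boundary-value problem assembled by :mod:`echobc.flow_split`:

* ``0/U`` — ``flowRateInletVelocity`` at the inlet patch and
  ``flowRateOutletVelocity`` at each outlet, both with a constant
  ``volumetricFlowRate``; ``noSlip`` at the wall.  These built-in
  conditions extrapolate the internal field to meet the prescribed flow
  rate rather than imposing a profile.
* ``0/p`` — ``zeroGradient`` kinematic pressure everywhere (with an
  optional zero-pressure-outlet variant used for grid studies), anchored
  by an internal reference (cell 0, value 0) in ``system/fvSolution``.
* ``constant/transportProperties`` — Newtonian blood, ν = 3.78e-6 m²/s.
* ``system/fvSchemes`` / ``system/fvSolution`` — second-order backward
  time scheme and a bounded second-order convective scheme.

Regeneration from the same :class:`~echobc.flow_split.BoundarySpec` is
byte-identical, and every written flow value can be parsed back exactly.
The keyword set targets the OpenFOAM 6 dialect.

The module also reads whitespace-delimited sampled-line output
(``postProcessing/sets`` raw format) into :class:`SampledProfile` objects
for the grid-independence check.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError, ParseError
from .flow_split import BoundarySpec
from .hemodynamics import FluidProperties
from .waveforms import Site

__all__ = [
    "DEFAULT_PATCH_NAMES",
    "SampledProfile",
    "render_velocity_bcs",
    "render_pressure_bcs",
    "render_transport_properties",
    "render_fv_schemes",
    "render_fv_solution",
    "write_case",
    "parse_flow_rates",
    "check_dictionary_syntax",
    "read_sampled_lines",
]

logger = logging.getLogger(__name__)

#: Default mapping from measurement sites to OpenFOAM patch names.
DEFAULT_PATCH_NAMES: Dict[Site, str] = {
    Site.ASCENDING_AORTA: "inlet",
    Site.INNOMINATE: "innominate",
    Site.LCCA: "lcca",
    Site.LSCA: "lsca",
    Site.DESCENDING_AORTA: "descending_aorta",
}

#: Canonical ordering of patches in written dictionaries.
_SITE_ORDER = [
    Site.ASCENDING_AORTA,
    Site.INNOMINATE,
    Site.LCCA,
    Site.LSCA,
    Site.DESCENDING_AORTA,
]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _foam_header(cls: str, obj: str, location: str) -> str:
    return (
        "FoamFile\n"
        "{\n"
        "    version     2.0;\n"
        "    format      ascii;\n"
        f"    class       {cls};\n"
        f'    location    "{location}";\n'
        f"    object      {obj};\n"
        "}\n\n"
    )


def _ordered_outlets(spec: BoundarySpec) -> List[Site]:
    return [s for s in _SITE_ORDER if s in spec.outlet_flows]


def render_velocity_bcs(
    spec: BoundarySpec,
    patch_names: Mapping[Site, str] = DEFAULT_PATCH_NAMES,
    wall_patch: str = "wall",
) -> str:
    """Render ``0/U`` for a :class:`BoundarySpec`.

    Flow values are written as positive magnitudes; the built-in
    flow-rate conditions handle the direction convention.
    """
    outlets = _ordered_outlets(spec)
    if not outlets:
        raise ConfigurationError("boundary spec has no outlets")
    missing = [s.value for s in outlets + [Site.ASCENDING_AORTA]
               if s not in patch_names]
    if missing:
        raise ConfigurationError(f"no patch name for sites: {', '.join(missing)}")
    lines = [_foam_header("volVectorField", "U", "0")]
    lines.append("dimensions      [0 1 -1 0 0 0 0];\n\n")
    lines.append("internalField   uniform (0 0 0);\n\n")
    lines.append("boundaryField\n{\n")
    lines.append(
        f"    {patch_names[Site.ASCENDING_AORTA]}\n"
        "    {\n"
        "        type            flowRateInletVelocity;\n"
        f"        volumetricFlowRate constant {_fmt(spec.inlet_flow)};\n"
        "        value           uniform (0 0 0);\n"
        "    }\n"
    )
    for site in outlets:
        lines.append(
            f"    {patch_names[site]}\n"
            "    {\n"
            "        type            flowRateOutletVelocity;\n"
            f"        volumetricFlowRate constant {_fmt(spec.outlet_flows[site])};\n"
            "        value           uniform (0 0 0);\n"
            "    }\n"
        )
    lines.append(
        f"    {wall_patch}\n"
        "    {\n"
        "        type            noSlip;\n"
        "    }\n"
    )
    lines.append("}\n")
    return "".join(lines)


def render_pressure_bcs(
    spec: BoundarySpec,
    patch_names: Mapping[Site, str] = DEFAULT_PATCH_NAMES,
    wall_patch: str = "wall",
    zero_pressure_outlets: bool = False,
) -> str:
    """Render ``0/p`` (kinematic pressure, m²/s²).

    Default: ``zeroGradient`` on every patch with the reference set in
    ``fvSolution``.  ``zero_pressure_outlets=True`` writes ``fixedValue 0``
    at outlets instead — the simplified setup used for grid studies.
    """
    outlets = _ordered_outlets(spec)
    lines = [_foam_header("volScalarField", "p", "0")]
    lines.append("dimensions      [0 2 -2 0 0 0 0];\n\n")
    lines.append("internalField   uniform 0;\n\n")
    lines.append("boundaryField\n{\n")
    lines.append(
        f"    {patch_names[Site.ASCENDING_AORTA]}\n"
        "    {\n"
        "        type            zeroGradient;\n"
        "    }\n"
    )
    for site in outlets:
        if zero_pressure_outlets:
            lines.append(
                f"    {patch_names[site]}\n"
                "    {\n"
                "        type            fixedValue;\n"
                "        value           uniform 0;\n"
                "    }\n"
            )
        else:
            lines.append(
                f"    {patch_names[site]}\n"
                "    {\n"
                "        type            zeroGradient;\n"
                "    }\n"
            )
    lines.append(
        f"    {wall_patch}\n"
        "    {\n"
        "        type            zeroGradient;\n"
        "    }\n"
    )
    lines.append("}\n")
    return "".join(lines)


def render_transport_properties(fluid: FluidProperties = FluidProperties()) -> str:
    """Render ``constant/transportProperties`` for Newtonian blood."""
    return (
        _foam_header("dictionary", "transportProperties", "constant")
        + "transportModel  Newtonian;\n\n"
        + f"nu              [0 2 -1 0 0 0 0] {_fmt(fluid.kinematic_viscosity)};\n"
    )


def render_fv_schemes() -> str:
    """Render ``system/fvSchemes``: backward Euler in time, bounded
    second-order upwind convection."""
    return (
        _foam_header("dictionary", "fvSchemes", "system")
        + "ddtSchemes\n{\n    default         backward;\n}\n\n"
        + "gradSchemes\n{\n    default         Gauss linear;\n}\n\n"
        + "divSchemes\n{\n"
        + "    default         none;\n"
        + "    div(phi,U)      bounded Gauss linearUpwind grad(U);\n"
        + "}\n\n"
        + "laplacianSchemes\n{\n    default         Gauss linear corrected;\n}\n\n"
        + "interpolationSchemes\n{\n    default         linear;\n}\n\n"
        + "snGradSchemes\n{\n    default         corrected;\n}\n"
    )


def render_fv_solution() -> str:
    """Render ``system/fvSolution`` with an internal pressure reference
    (cell 0, value 0)."""
    return (
        _foam_header("dictionary", "fvSolution", "system")
        + "solvers\n{\n"
        + "    p\n    {\n"
        + "        solver          GAMG;\n"
        + "        smoother        GaussSeidel;\n"
        + "        tolerance       1e-06;\n"
        + "        relTol          0.01;\n"
        + "    }\n\n"
        + "    U\n    {\n"
        + "        solver          smoothSolver;\n"
        + "        smoother        symGaussSeidel;\n"
        + "        tolerance       1e-06;\n"
        + "        relTol          0.1;\n"
        + "    }\n"
        + "}\n\n"
        + "SIMPLE\n{\n"
        + "    nNonOrthogonalCorrectors 1;\n"
        + "    pRefCell        0;\n"
        + "    pRefValue       0;\n"
        + "}\n\n"
        + "relaxationFactors\n{\n"
        + "    fields\n    {\n        p               0.3;\n    }\n"
        + "    equations\n    {\n        U               0.7;\n    }\n"
        + "}\n"
    )


def write_case(
    spec: BoundarySpec,
    case_dir: Union[str, Path],
    patch_names: Mapping[Site, str] = DEFAULT_PATCH_NAMES,
    wall_patch: str = "wall",
    zero_pressure_outlets: bool = False,
) -> Dict[str, Path]:
    """Write the case skeleton (0/U, 0/p, constant/transportProperties,
    system/fvSchemes, system/fvSolution) and return the written paths.

    Rewriting from an identical spec produces byte-identical files.
    """
    case_dir = Path(case_dir)
    files = {
        "0/U": render_velocity_bcs(spec, patch_names, wall_patch),
        "0/p": render_pressure_bcs(
            spec, patch_names, wall_patch, zero_pressure_outlets
        ),
        "constant/transportProperties": render_transport_properties(spec.fluid),
        "system/fvSchemes": render_fv_schemes(),
        "system/fvSolution": render_fv_solution(),
    }
    written: Dict[str, Path] = {}
    for rel, text in files.items():
        path = case_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        written[rel] = path
    return written


_FLOW_RE = re.compile(
    r"^\s*(\S+)\s*\n\s*\{([^}]*)\}", re.MULTILINE
)
_RATE_RE = re.compile(r"volumetricFlowRate\s+constant\s+([^;]+);")
_TYPE_RE = re.compile(r"type\s+(\S+);")


def parse_flow_rates(u_file_text: str) -> Tuple[float, Dict[str, float]]:
    """Parse a written ``0/U`` file back into ``(inlet_flow,
    {outlet_patch: flow})``; the exact inverse of
    :func:`render_velocity_bcs` for the flow values."""
    inlet = None
    outlets: Dict[str, float] = {}
    for match in _FLOW_RE.finditer(u_file_text):
        name, body = match.group(1), match.group(2)
        type_m = _TYPE_RE.search(body)
        rate_m = _RATE_RE.search(body)
        if type_m is None or rate_m is None:
            continue
        value = float(rate_m.group(1))
        if type_m.group(1) == "flowRateInletVelocity":
            inlet = value
        elif type_m.group(1) == "flowRateOutletVelocity":
            outlets[name] = value
    if inlet is None:
        raise ParseError("no flowRateInletVelocity entry found")
    return inlet, outlets


def check_dictionary_syntax(text: str) -> bool:
    """Light grammar check of an OpenFOAM dictionary: braces balance and
    every entry line is terminated by ``;``, ``{`` or ``}`` (bare keyword
    lines that open a sub-dictionary are allowed)."""
    depth = 0
    for raw in text.splitlines():
        line = raw.split("//")[0].strip()
        if not line:
            continue
        depth += line.count("{") - line.count("}")
        if depth < 0:
            return False
        if line.endswith(("{", "}", ";")):
            continue
        # a bare token (keyword or sub-dict name) is fine; anything with
        # multiple tokens must be ';'-terminated
        if len(line.split()) > 1:
            return False
    return depth == 0


# ---------------------------------------------------------------------------
# sampled post-processing output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampledProfile:
    """Values sampled along one line (station) of a CFD solution.

    ``position`` in metres along the line, ``pressure`` kinematic (m²/s²),
    ``velocity`` magnitude (m/s).  Positions are strictly increasing.
    """

    station: str
    position: np.ndarray
    pressure: np.ndarray
    velocity: np.ndarray
    mesh_label: str = ""

    def __post_init__(self) -> None:
        for name in ("position", "pressure", "velocity"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        n = self.position.size
        if self.pressure.size != n or self.velocity.size != n:
            raise ParseError("position, pressure and velocity lengths differ")
        if not np.all(np.diff(self.position) > 0):
            raise ParseError("positions must be strictly increasing")


def read_sampled_lines(
    files: Union[Mapping[str, Union[str, Path]], Iterable[Union[str, Path]]],
    mesh_label: str,
    columns: Tuple[int, int, int] = (0, 1, 2),
) -> List[SampledProfile]:
    """Read whitespace-delimited sampled-line files into profiles.

    ``files`` maps station labels to paths, or is an iterable of paths whose
    stems name the stations.  ``columns`` gives the (position, pressure,
    velocity-magnitude) column indices.  Rows with a differing column count
    raise :class:`ParseError` with the line number; non-monotone positions
    are sorted with a logged warning.
    """
    if isinstance(files, Mapping):
        items = list(files.items())
    else:
        items = [(Path(p).stem, p) for p in files]
    profiles: List[SampledProfile] = []
    for station, path in items:
        rows: List[List[float]] = []
        ncol_expected = None
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncol_expected is None:
                ncol_expected = len(parts)
                if ncol_expected <= max(columns):
                    raise ParseError(
                        f"{path}: line {lineno}: need at least "
                        f"{max(columns) + 1} columns, got {ncol_expected}"
                    )
            elif len(parts) != ncol_expected:
                raise ParseError(
                    f"{path}: line {lineno}: ragged row "
                    f"({len(parts)} columns, expected {ncol_expected})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric value")
        if not rows:
            raise ParseError(f"{path}: no data rows")
        arr = np.asarray(rows, dtype=float)
        pos = arr[:, columns[0]]
        if not np.all(np.diff(pos) > 0):
            logger.warning(
                "%s: positions not monotone for station %r; sorting", path, station
            )
            order = np.argsort(pos, kind="stable")
            arr = arr[order]
            pos = arr[:, columns[0]]
        profiles.append(
            SampledProfile(
                station=station,
                position=pos,
                pressure=arr[:, columns[1]],
                velocity=arr[:, columns[2]],
                mesh_label=mesh_label,
            )
        )
    return profiles
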