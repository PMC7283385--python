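"""End-to-end orchestration: waveform files in, case directory out.

The three commands mirror the stages of the study protocol:

``process_echo``
    Smooth and period-normalise every site waveform, convert to volumetric
    flow, and tabulate peak velocity, simplified-Bernoulli pressure and
    measured diameter per site.

``build_case``
    Derive the mass-consistent outlet set for the configured data regime,
    extract steady peak-systolic boundary values, and write the OpenFOAM
    case skeleton plus a boundary report and a machine-readable run
    manifest (seeds, derived factors, assumptions).

``grid_check``
    Read sampled-line files for two or more meshes and run the
    grid-independence assessment.

Configuration comes from a single :class:`PipelineConfig`, loadable from a
YAML file with per-command sections so a clinical run is auditable from one
document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .flow_split import (
    BoundarySpec,
    CaseMode,
    SplitFactors,
    branch_ratios_from,
    conserve_mass_scale,
    derive_case2_outlets,
    derive_case3_outlets,
    extract_steady_bcs,
    write_boundary_report,
)
from .grid_check import GridCheckReport, assess
from .hemodynamics import (
    FlowWaveform,
    FluidProperties,
    VelocityProfile,
    bernoulli_pressure_mmHg,
    circular_area,
    velocity_to_flow,
)
from .openfoam import read_sampled_lines, write_case
from .waveforms import (
    BRANCH_SITES,
    DEFAULT_PERIOD_S,
    INLET_SITE,
    OUTLET_SITES,
    Site,
    VelocityWaveform,
    normalize_period,
    peak_of,
    read_waveform,
    smooth_waveform,
)

__all__ = [
    "DEFAULT_SMOOTH_WINDOW",
    "PipelineConfig",
    "processed_flow",
    "process_echo",
    "build_case",
    "grid_check",
    "echo_report",
]

logger = logging.getLogger(__name__)

#: Default smoothing window (samples) for digitised envelopes.
DEFAULT_SMOOTH_WINDOW = 7

_MODE_REQUIRED_SITES: Dict[CaseMode, Tuple[Site, ...]] = {
    CaseMode.FULL_DATA: (INLET_SITE,) + OUTLET_SITES,
    CaseMode.PARTIAL_POST_REPAIR: (INLET_SITE, Site.INNOMINATE),
    CaseMode.HYPOTHETICAL_HEALTHY: (INLET_SITE,),
}


@dataclass
class PipelineConfig:
    """Everything one run needs, resolvable from a single YAML document."""

    mode: CaseMode = CaseMode.FULL_DATA
    waveform_files: Dict[Site, Path] = field(default_factory=dict)
    diameters_mm: Dict[Site, float] = field(default_factory=dict)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    factors: SplitFactors = field(default_factory=lambda: SplitFactors())
    output_dir: Path = Path("echobc_out")
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    target_period_s: float = DEFAULT_PERIOD_S
    descending_fraction: float = 0.70
    grid_threshold: float = 0.05
    mesh_files: Dict[str, Dict[str, Path]] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        cfg = cls()
        if "mode" in raw:
            cfg.mode = CaseMode(raw["mode"])
        for s, f in (raw.get("waveform_files") or {}).items():
            cfg.waveform_files[Site(s)] = base / f
        for s, d in (raw.get("diameters_mm") or {}).items():
            cfg.diameters_mm[Site(s)] = float(d)
        if "fluid" in raw:
            cfg.fluid = FluidProperties(**raw["fluid"])
        fac = raw.get("factors") or {}
        cfg.factors = SplitFactors(
            outlet_scale=fac.get("outlet_scale"),
            descending_inlet_scale=fac.get("descending_inlet_scale"),
            descending_fraction=fac.get(
                "descending_fraction", raw.get("descending_fraction", 0.70)
            ),
            branch_ratios={
                Site(s): float(r)
                for s, r in (fac.get("branch_ratios") or {}).items()
            },
        )
        for key, attr in (
            ("output_dir", "output_dir"),
        ):
            if key in raw:
                setattr(cfg, attr, base / raw[key])
        for key in (
            "smooth_window",
            "target_period_s",
            "descending_fraction",
            "grid_threshold",
            "seed",
        ):
            if key in raw:
                setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
        for mesh, stations in (raw.get("mesh_files") or {}).items():
            cfg.mesh_files[mesh] = {st: base / f for st, f in stations.items()}
        return cfg

    @classmethod
    def from_patient_dir(
        cls, directory: Union[str, Path], **overrides
    ) -> "PipelineConfig":
        """Build a config from a patient directory written by
        :func:`echobc.synthetic.write_patient`."""
        directory = Path(directory)
        manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
        gt = manifest.get("ground_truth") or {}
        cfg = cls(
            mode=CaseMode(manifest["scenario"]),
            waveform_files={
                Site(s): directory / f
                for s, f in manifest["waveform_files"].items()
            },
            diameters_mm={
                Site(s): float(d) for s, d in manifest["diameters_mm"].items()
            },
            factors=SplitFactors(
                outlet_scale=gt.get("outlet_scale"),
                descending_fraction=gt.get("descending_fraction", 0.70),
                branch_ratios={
                    Site(s): float(r)
                    for s, r in (gt.get("branch_ratios") or {}).items()
                },
            ),
            seed=int(manifest.get("seed", 0)),
        )
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg


def processed_flow(
    w: VelocityWaveform,
    diameter_mm: float,
    *,
    inlet: bool,
    window: int = DEFAULT_SMOOTH_WINDOW,
    target_period: float = DEFAULT_PERIOD_S,
) -> FlowWaveform:
    """Standard per-site chain: smooth → normalise period → convert to flow.

    The inlet uses the parabolic-profile assumption (average velocity is
    half the envelope); outlets take the envelope as the average.  Patch
    areas come from the measured diameter assuming a circular section.
    """
    w = smooth_waveform(w, window)
    w = normalize_period(w, target_period)
    profile = (
        VelocityProfile.PARABOLIC_HALF_MAX if inlet else VelocityProfile.MAX_EQUALS_AVG
    )
    return velocity_to_flow(w, circular_area(diameter_mm), profile)


def _load_waveforms(config: PipelineConfig) -> Dict[Site, VelocityWaveform]:
    waveforms: Dict[Site, VelocityWaveform] = {}
    for site, path in config.waveform_files.items():
        if not Path(path).exists():
            raise ConfigurationError(f"waveform file not found: {path}")
        waveforms[site] = read_waveform(path)
    required = _MODE_REQUIRED_SITES[config.mode]
    missing = [s.value for s in required if s not in waveforms]
    if missing:
        raise ConfigurationError(
            f"mode {config.mode.value} requires waveforms for: {', '.join(missing)}"
        )
    return waveforms


def echo_report(
    waveforms: Mapping[Site, VelocityWaveform],
    diameters_mm: Mapping[Site, float],
    window: int = DEFAULT_SMOOTH_WINDOW,
    target_period: float = DEFAULT_PERIOD_S,
) -> pd.DataFrame:
    """Per-site summary: peak velocity, simplified-Bernoulli ΔP = 4v²
    (mmHg), measured diameter."""
    rows = []
    for site in Site:
        if site not in waveforms:
            continue
        w = normalize_period(smooth_waveform(waveforms[site], window), target_period)
        _, v_max = peak_of(w)
        rows.append(
            {
                "site": site.value,
                "max_velocity_m_s": v_max,
                "max_pressure_difference_mmHg": bernoulli_pressure_mmHg(v_max),
                "measured_diameter_mm": diameters_mm.get(site),
            }
        )
    return pd.DataFrame(rows)


def process_echo(config: PipelineConfig) -> Dict[str, object]:
    """Run the waveform-processing stage; writes processed waveforms and a
    per-site report under ``output_dir`` and returns them."""
    from .waveforms import write_waveform

    waveforms = _load_waveforms(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    processed: Dict[Site, VelocityWaveform] = {}
    flows: Dict[Site, FlowWaveform] = {}
    for site, w in waveforms.items():
        pw = normalize_period(
            smooth_waveform(w, config.smooth_window), config.target_period_s
        )
        processed[site] = pw
        write_waveform(pw, outdir / f"{site.value}_processed.txt")
        if site in config.diameters_mm:
            flows[site] = processed_flow(
                w,
                config.diameters_mm[site],
                inlet=(site is INLET_SITE),
                window=config.smooth_window,
                target_period=config.target_period_s,
            )
    report = echo_report(
        waveforms, config.diameters_mm, config.smooth_window, config.target_period_s
    )
    report.to_csv(outdir / "echo_report.csv", index=False)
    logger.info("processed %d sites -> %s", len(processed), outdir)
    return {"waveforms": processed, "flows": flows, "report": report}


def _derive_outlets(
    config: PipelineConfig,
    waveforms: Mapping[Site, VelocityWaveform],
) -> Tuple[FlowWaveform, List[FlowWaveform], SplitFactors]:
    mode = config.mode
    inlet_d = config.diameters_mm.get(INLET_SITE)
    if inlet_d is None:
        raise ConfigurationError("inlet (ascending aorta) diameter is required")
    inlet = processed_flow(
        waveforms[INLET_SITE],
        inlet_d,
        inlet=True,
        window=config.smooth_window,
        target_period=config.target_period_s,
    )
    if mode is CaseMode.FULL_DATA:
        outlets = []
        for site in OUTLET_SITES:
            if site not in config.diameters_mm:
                raise ConfigurationError(f"diameter missing for outlet {site.value}")
            outlets.append(
                processed_flow(
                    waveforms[site],
                    config.diameters_mm[site],
                    inlet=False,
                    window=config.smooth_window,
                    target_period=config.target_period_s,
                )
            )
        scaled, factor = conserve_mass_scale(inlet, outlets)
        factors = SplitFactors(
            outlet_scale=factor,
            descending_fraction=config.descending_fraction,
            branch_ratios=branch_ratios_from(scaled),
        )
        logger.info("uniform outlet mass-conservation factor: %.4f", factor)
        return inlet, scaled, factors
    if mode is CaseMode.PARTIAL_POST_REPAIR:
        if config.factors.outlet_scale is None:
            raise ConfigurationError(
                "partial_post_repair needs the full-data outlet_scale "
                "(factors.outlet_scale)"
            )
        inn = processed_flow(
            waveforms[Site.INNOMINATE],
            config.diameters_mm[Site.INNOMINATE],
            inlet=False,
            window=config.smooth_window,
            target_period=config.target_period_s,
        )
        outlets, factors = derive_case2_outlets(config.factors, inlet, inn)
        logger.info(
            "solved descending-aorta inlet scale: %.4f",
            factors.descending_inlet_scale,
        )
        return inlet, outlets, factors
    # hypothetical healthy
    areas = {
        s: circular_area(config.diameters_mm[s])
        for s in BRANCH_SITES
        if s in config.diameters_mm
    }
    outlets = derive_case3_outlets(inlet, areas, config.descending_fraction)
    factors = SplitFactors(descending_fraction=config.descending_fraction)
    logger.info(
        "healthy split: %.0f%% descending, branches by area ratio",
        100 * config.descending_fraction,
    )
    return inlet, outlets, factors


def build_case(config: PipelineConfig) -> Dict[str, object]:
    """Derive the :class:`BoundarySpec` for the configured regime and write
    the OpenFOAM case, boundary report and run manifest."""
    waveforms = _load_waveforms(config)
    inlet, outlets, factors = _derive_outlets(config, waveforms)
    spec = extract_steady_bcs(inlet, outlets, config.fluid)
    outdir = Path(config.output_dir)
    case_dir = outdir / "case"
    written = write_case(spec, case_dir)
    write_boundary_report(spec, outdir / "boundary_report.yaml", factors)
    manifest = {
        "echobc_version": __version__,
        "mode": config.mode.value,
        "seed": config.seed,
        "smooth_window": config.smooth_window,
        "target_period_s": config.target_period_s,
        "factors": {
            "outlet_scale": factors.outlet_scale,
            "descending_inlet_scale": factors.descending_inlet_scale,
            "descending_fraction": factors.descending_fraction,
            "branch_ratios": {
                Site(s).value: r for s, r in factors.branch_ratios.items()
            },
        },
        "notes": [
            "inlet flow written as the sum of outlet steady values "
            "(mass-conservation contract)",
        ],
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("case written to %s", case_dir)
    return {
        "spec": spec,
        "factors": factors,
        "case_files": written,
        "manifest": manifest,
    }


def grid_check(config: PipelineConfig) -> GridCheckReport:
    """Run the grid-independence assessment on the configured mesh files."""
    if len(config.mesh_files) < 2:
        raise ConfigurationError("grid check needs sampled files for >= 2 meshes")
    meshes = {
        label: read_sampled_lines(stations, mesh_label=label)
        for label, stations in config.mesh_files.items()
    }
    report = assess(meshes, threshold=config.grid_threshold, fluid=config.fluid)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "grid_check.csv")
    (outdir / "grid_check.txt").write_text(report.summary() + "\n")
    logger.info("grid check: %s", "PASS" if report.passed else "FAIL")
    return report
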