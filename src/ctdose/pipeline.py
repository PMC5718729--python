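"""End-to-end workflow: commissioning synthesis/validation -> phantom ->
engine dose -> optional Monte Carlo -> comparison report, with a
provenance record (inputs, output hashes, seed, version)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, beam_model, dose_engine, kv_mc, phantom, reporting
from .errors import CTDoseError, PipelineError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "ctdose_run"
    seed: int = 0
    # phantom: either a preset name or a path to an .mhd volume (+ markers csv)
    phantom_preset: str = "newborn"
    phantom_path: str | None = None
    markers_path: str | None = None
    # model: path to a manifest, or None to synthesize
    model_manifest: str | None = None
    # scan technique
    kvp: float = 120.0
    mAs: float = 100.0
    bowtie: str = "head"
    beam_width: float = 10.0
    n_beams: int = 16
    n_slices: int = 5
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    # MC arm; 0 disables
    n_histories: int = 100_000


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the artifact manifest (also
    written to ``provenance.json``).  Any stage failure raises
    :class:`PipelineError` labeled with the stage name."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    extras: dict[str, object] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except CTDoseError as exc:
                raise PipelineError(name, str(exc)) from exc
            except FileNotFoundError as exc:
                raise PipelineError(name, str(exc)) from exc
        return deco

    @stage("commissioning")
    def model():
        if config.model_manifest:
            m = beam_model.load_beam_model(config.model_manifest)
        else:
            params = beam_model.SyntheticBeamParams(
                kvp=config.kvp, bowtie=config.bowtie,
                beam_width=config.beam_width)
            m = beam_model.generate_synthetic_beam_model(params, seed=config.seed)
        manifest = beam_model.save_beam_model(m, out / "model")
        artifacts["model_manifest"] = str(manifest)
        return m

    @stage("phantom")
    def built():
        if config.phantom_path:
            grid = phantom.read_volume(config.phantom_path)
            if not config.markers_path:
                raise PipelineError("phantom", "markers_path required with phantom_path")
            markers = phantom.read_markers(config.markers_path)
        else:
            params = phantom.CHEST_PRESETS[config.phantom_preset]
            params = phantom.ChestParams(**{**vars(params), "spacing": config.spacing})
            grid, markers = phantom.make_chest_phantom(
                params=params, seed=config.seed)
        markers.validate(grid)
        phantom.write_volume(grid, out / "phantom.mhd")
        phantom.write_markers(markers, out / "markers.csv")
        artifacts["phantom"] = str(out / "phantom.mhd")
        artifacts["markers"] = str(out / "markers.csv")
        return grid, markers

    grid, markers = built
    density = phantom.hu_to_density(grid)

    half = (config.n_slices - 1) / 2.0 * config.beam_width
    spec = dose_engine.ScanSpec(
        kvp=config.kvp, mAs_per_rotation=config.mAs, bowtie=config.bowtie,
        beam_width=config.beam_width, n_beams=config.n_beams,
        slice_z_positions=tuple(-half + i * config.beam_width
                                for i in range(config.n_slices)))

    @stage("engine-dose")
    def engine_abs():
        rel = dose_engine.multislice_scan_dose(density, spec, model)
        dose, report = dose_engine.calibrate_absolute(
            rel, density, spec, model, return_report=True)
        phantom.write_volume(
            phantom.VoxelGrid(values=dose.values, spacing=dose.spacing,
                              origin=dose.origin, value_kind="density"),
            out / "dose_engine.mhd")
        artifacts["engine_dose"] = str(out / "dose_engine.mhd")
        extras["calibration"] = vars(report)
        log.info("engine calibration: %s", vars(report))
        return dose

    mc_abs = None
    if config.n_histories > 0:
        @stage("monte-carlo")
        def _mc():
            res = kv_mc.run_mc_scan(density, spec, model,
                                    n_histories=config.n_histories,
                                    seed=config.seed)
            dose = dose_engine.calibrate_absolute(res.dose, density, spec, model)
            dose.sigma = res.sigma
            phantom.write_volume(
                phantom.VoxelGrid(values=dose.values, spacing=dose.spacing,
                                  origin=dose.origin, value_kind="density"),
                out / "dose_mc.mhd")
            phantom.write_volume(
                phantom.VoxelGrid(values=res.sigma, spacing=dose.spacing,
                                  origin=dose.origin, value_kind="density"),
                out / "sigma_mc.mhd")
            artifacts["mc_dose"] = str(out / "dose_mc.mhd")
            artifacts["mc_sigma"] = str(out / "sigma_mc.mhd")
            return dose
        mc_abs = _mc

    @stage("reporting")
    def _report():
        if mc_abs is not None:
            rows = reporting.comparison_table(engine=engine_abs, mc=mc_abs,
                                              markers=markers)
        else:
            doses = reporting.marker_dose(engine_abs, markers)
            rows = [reporting.ComparisonRow(label=lab, dose_engine=d,
                                            sd_engine=sd)
                    for lab, (d, sd) in doses.items()]
        reporting.write_report(rows, out / "report.csv")
        artifacts["report"] = str(out / "report.csv")
        return rows

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "artifacts": artifacts,
        "calibration": extras.get("calibration"),
        "hashes": {k: _sha256(Path(v)) for k, v in artifacts.items()
                   if Path(v).exists()},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return provenance
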