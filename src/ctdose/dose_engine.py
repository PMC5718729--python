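"""Semi-empirical rotational fan-beam dose engine.

The dose at a voxel center p from one fan beam is

    D(p) = TMR(d_eff(p)) * Px(x_off(p)) * Pz(z_off(p)) * (SID / r(p))**2

where d_eff is the radiological (electron-density-scaled) depth along the
source->p ray, Px/Pz are the measured crossbeam profiles evaluated at the
offsets of p projected along the ray onto the isocenter plane, and the last
factor is the inverse-square correction referenced to the source-to-
isocenter distance SID.  Scatter is not modeled by an explicit kernel: the
TMR and profiles are broad-beam measured quantities, so scatter is folded
into the commissioning data; heterogeneity correction enters only through
the density-scaled depth of the TMR lookup.

An axial rotation superposes beams at equal angular increments; a
multi-slice scan superposes rotations over couch positions and is
normalized by the global maximum voxel dose.  Absolute calibration anchors
the relative value at the isocenter to the CTDI100 reference table at the
rotationally averaged isocenter depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _tracing
from .beam_model import BeamModel, ctdi_reference, interp_tmr, tmr_tail_mu
from .errors import (CalibrationError, ConfigurationError, DomainError,
                     NormalizationError)
from .phantom import VoxelGrid

log = logging.getLogger(__name__)


@dataclass
class ScanSpec:
    """Axial CT acquisition to simulate."""

    kvp: float = 120.0
    mAs_per_rotation: float = 100.0
    bowtie: str = "head"
    beam_width: float = 10.0
    n_beams: int = 16
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_z_positions: tuple[float, ...] = (0.0,)
    sid: float = 541.0

    def __post_init__(self):
        if self.n_beams < 4:
            raise ConfigurationError("n_beams must be >= 4")
        self.slice_z_positions = tuple(float(z) for z in self.slice_z_positions)

    @classmethod
    def contiguous(cls, z_start: float, z_stop: float, beam_width: float = 10.0,
                   **kwargs) -> "ScanSpec":
        """Contiguous axial slices spaced by the beam width."""
        n = max(int(round((z_stop - z_start) / beam_width)) + 1, 1)
        zs = tuple(z_start + i * beam_width for i in range(n))
        return cls(beam_width=beam_width, slice_z_positions=zs, **kwargs)


@dataclass
class DoseGrid:
    """Dose volume co-registered with its phantom grid."""

    values: np.ndarray  # (nx, ny, nz)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    kind: str = "relative"  # "relative" | "absolute" (mGy/100 mAs)
    sigma: np.ndarray | None = None  # per-voxel relative standard deviation

    @property
    def shape(self):
        return self.values.shape

    def point_value(self, point) -> float:
        """Trilinear sample at a world point."""
        f = (np.asarray(point, dtype=float) - np.asarray(self.origin)) \
            / np.asarray(self.spacing)
        i0 = np.floor(f).astype(int)
        w = f - i0
        n = np.asarray(self.shape)
        i0 = np.clip(i0, 0, n - 2)
        w = np.clip(f - i0, 0.0, 1.0)
        v = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = ((dx * w[0] + (1 - dx) * (1 - w[0]))
                          * (dy * w[1] + (1 - dy) * (1 - w[1]))
                          * (dz * w[2] + (1 - dz) * (1 - w[2])))
                    v += wt * self.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        return float(v)


@dataclass
class EngineOptions:
    inverse_square: bool = True
    profile_cutoff: float = 1e-5  # skip voxels whose profile product is below
    surface_threshold: float = 0.2  # density defining the body surface
    depth_ray_step: float | None = None  # average-depth sampling step (mm)
    supersample: int = 1  # 2 -> average the beam over 2x2x2 sub-voxel points


@dataclass
class CalibrationReport:
    average_depth_mm: float
    ctdi_reference_mGy_100mAs: float
    relative_dose_at_isocenter: float
    factor: float


def _require_commissioned(spec: ScanSpec, model: BeamModel) -> None:
    if (spec.kvp, spec.bowtie, spec.beam_width) != \
            (model.kvp, model.bowtie, model.beam_width):
        raise ConfigurationError(
            f"technique ({spec.kvp} kVp, {spec.bowtie}, {spec.beam_width} mm) "
            f"not commissioned; model is ({model.kvp}, {model.bowtie}, "
            f"{model.beam_width})")


def _require_density(grid: VoxelGrid) -> None:
    if grid.value_kind != "density":
        raise ConfigurationError(
            "dose engine needs a density grid; run hu_to_density first")


# ---------------------------------------------------------------------------
# radiological depth


def radiological_depth(density: VoxelGrid, src, pt) -> float:
    """Water-equivalent depth (mm): line integral of relative electron
    density from the phantom entry to ``pt`` along the ray src->pt."""
    _require_density(density)
    if density.contains_point(src):
        raise DomainError("source must lie outside the phantom volume")
    if not density.contains_point(pt):
        raise DomainError("target point outside the grid bounds")
    lo, _ = density.bounds()
    sx, sy, sz = (float(c) for c in np.asarray(src, dtype=float))
    px, py, pz = (float(c) for c in np.asarray(pt, dtype=float))
    return float(_tracing.ray_depth(
        np.ascontiguousarray(density.values, dtype=np.float64),
        density.spacing[0], density.spacing[1], density.spacing[2],
        lo[0], lo[1], lo[2], sx, sy, sz, px, py, pz))


# ---------------------------------------------------------------------------
# beam superposition


def _model_arrays(model: BeamModel):
    return (np.ascontiguousarray(model.tmr.depths, dtype=np.float64),
            np.ascontiguousarray(model.tmr.values, dtype=np.float64),
            tmr_tail_mu(model.tmr),
            np.ascontiguousarray(model.profile_x.offsets, dtype=np.float64),
            np.ascontiguousarray(model.profile_x.values, dtype=np.float64),
            np.ascontiguousarray(model.profile_z.offsets, dtype=np.float64),
            np.ascontiguousarray(model.profile_z.values, dtype=np.float64))


def _add_beam(out: np.ndarray, dens: np.ndarray, density: VoxelGrid,
              angle_deg: float, z: float, spec: ScanSpec, model: BeamModel,
              options: EngineOptions) -> None:
    theta = math.radians(angle_deg)
    iso = np.asarray(spec.isocenter, dtype=float)
    sid = spec.sid
    src = iso + np.array([sid * math.cos(theta), sid * math.sin(theta), 0.0])
    src[2] = z
    if density.contains_point(src):
        raise DomainError("beam source falls inside the phantom grid; "
                          "increase SID or shrink the grid")
    ux = (iso[0] - src[0]) / sid
    uy = (iso[1] - src[1]) / sid
    tmr_d, tmr_v, tail_mu, pxo, pxv, pzo, pzv = _model_arrays(model)
    n_sub = max(int(options.supersample), 1)
    if n_sub == 1:
        offsets = [(0.0, 0.0, 0.0)]
    else:
        # symmetric sub-voxel lattice, e.g. +-1/4 voxel for n_sub = 2
        f = [(2 * i + 1) / (2 * n_sub) - 0.5 for i in range(n_sub)]
        offsets = [(fx, fy, fz) for fx in f for fy in f for fz in f]
    weight = 1.0 / len(offsets)
    if weight < 1.0:
        buf = np.zeros_like(out)
    for fx, fy, fz in offsets:
        target = out if weight == 1.0 else buf
        _tracing.beam_kernel(dens,
                             density.spacing[0], density.spacing[1],
                             density.spacing[2],
                             density.origin[0] + fx * density.spacing[0],
                             density.origin[1] + fy * density.spacing[1],
                             density.origin[2] + fz * density.spacing[2],
                             src[0], src[1], src[2], ux, uy, sid,
                             tmr_d, tmr_v, tail_mu, pxo, pxv, pzo, pzv,
                             options.inverse_square, options.profile_cutoff,
                             target)
    if weight < 1.0:
        out += weight * buf


def single_beam_dose(density: VoxelGrid, angle_deg: float, z: float,
                     spec: ScanSpec, model: BeamModel,
                     options: EngineOptions | None = None) -> DoseGrid:
    """Relative dose of one fan beam at gantry angle ``angle_deg`` (degrees,
    source position angle measured from +x) and couch position ``z``."""
    _require_density(density)
    _require_commissioned(spec, model)
    options = options or EngineOptions()
    dens = np.ascontiguousarray(density.values, dtype=np.float64)
    out = np.zeros(density.shape, dtype=np.float64)
    _add_beam(out, dens, density, angle_deg, z, spec, model, options)
    return DoseGrid(values=out, spacing=density.spacing, origin=density.origin,
                    kind="relative")


def axial_rotational_dose(density: VoxelGrid, z: float, spec: ScanSpec,
                          model: BeamModel,
                          options: EngineOptions | None = None) -> DoseGrid:
    """Equal-weight sum of single-beam doses over ``spec.n_beams`` angles at
    360/n increments (relative, unnormalized)."""
    _require_density(density)
    _require_commissioned(spec, model)
    options = options or EngineOptions()
    dens = np.ascontiguousarray(density.values, dtype=np.float64)
    out = np.zeros(density.shape, dtype=np.float64)
    step = 360.0 / spec.n_beams
    for b in range(spec.n_beams):
        _add_beam(out, dens, density, b * step, z, spec, model, options)
    return DoseGrid(values=out, spacing=density.spacing, origin=density.origin,
                    kind="relative")


def multislice_scan_dose(density: VoxelGrid, spec: ScanSpec, model: BeamModel,
                         options: EngineOptions | None = None) -> DoseGrid:
    """Superpose rotations over all couch positions, then normalize by the
    global maximum voxel dose within the body (ties broken at the lowest
    linear index).

    The maximum is taken over voxels above the surface density threshold:
    the semi-empirical formula extrapolates into surrounding air, where the
    inverse-square factor can exceed the in-body maximum without physical
    meaning, so normalization follows the maximum of the body scan.
    """
    if not spec.slice_z_positions:
        raise ConfigurationError("slice_z_positions must be non-empty")
    _require_density(density)
    _require_commissioned(spec, model)
    options = options or EngineOptions()
    dens = np.ascontiguousarray(density.values, dtype=np.float64)
    out = np.zeros(density.shape, dtype=np.float64)
    step = 360.0 / spec.n_beams
    for z in spec.slice_z_positions:
        for b in range(spec.n_beams):
            _add_beam(out, dens, density, b * step, z, spec, model, options)
    body = density.values > options.surface_threshold
    ref = out[body] if np.any(body) else out
    mx = float(ref.max())
    if mx <= 0.0:
        raise NormalizationError("zero dose everywhere; cannot normalize")
    flat = np.where(body, out, -1.0) if np.any(body) else out
    imax = int(np.argmax(flat))  # first (lowest linear index) maximum
    log.info("global maximum at linear voxel %d = %s", imax,
             np.unravel_index(imax, out.shape))
    out /= mx
    return DoseGrid(values=out, spacing=density.spacing, origin=density.origin,
                    kind="relative")


# ---------------------------------------------------------------------------
# average isocenter depth and absolute calibration


def average_isocenter_depth(density: VoxelGrid, isocenter, z: float,
                            n_rays: int = 360,
                            threshold: float = 0.2,
                            step: float | None = None) -> float:
    """Average distance from the isocenter to the outermost body-surface
    crossing over a full in-plane rotation (``n_rays`` equally spaced rays).

    The surface is the outermost sample with density above ``threshold``;
    the crossing is taken midway between that sample and the next one out.
    """
    _require_density(density)
    iso = np.asarray(isocenter, dtype=float)
    iso[2] = z
    if step is None:
        step = 0.25 * min(density.spacing[0], density.spacing[1])
    lo, hi = density.bounds()
    if not density.contains_point(iso):
        raise DomainError("isocenter outside the grid")
    # nearest-voxel density at the isocenter itself
    idx = np.clip(np.round(density.world_to_index(iso)).astype(int), 0,
                  np.asarray(density.shape) - 1)
    if density.values[tuple(idx)] <= threshold:
        raise DomainError("isocenter lies outside the body "
                          f"(density <= {threshold})")
    max_r = float(np.hypot(hi[0] - lo[0], hi[1] - lo[1]))
    n_samp = int(max_r / step) + 2
    radii = step * (np.arange(n_samp) + 1.0)
    ang = 2.0 * np.pi * np.arange(n_rays) / n_rays
    xs = iso[0] + np.cos(ang)[:, None] * radii[None, :]
    ys = iso[1] + np.sin(ang)[:, None] * radii[None, :]
    ii = np.round((xs - density.origin[0]) / density.spacing[0]).astype(int)
    jj = np.round((ys - density.origin[1]) / density.spacing[1]).astype(int)
    kk = int(np.clip(round((z - density.origin[2]) / density.spacing[2]), 0,
                     density.shape[2] - 1))
    inside = ((ii >= 0) & (ii < density.shape[0])
              & (jj >= 0) & (jj < density.shape[1]))
    vals = np.zeros_like(xs)
    vals[inside] = density.values[ii[inside], jj[inside], kk]
    above = vals > threshold
    # outermost sample above threshold per ray; crossing midway to next sample
    rev_any = above.any(axis=1)
    last = np.where(rev_any,
                    above.shape[1] - 1 - np.argmax(above[:, ::-1], axis=1), -1)
    depths = np.where(last >= 0, radii[np.clip(last, 0, None)] + 0.5 * step, 0.0)
    return float(depths.mean())


def calibrate_absolute(rel: DoseGrid, density: VoxelGrid, spec: ScanSpec,
                       model: BeamModel,
                       options: EngineOptions | None = None,
                       return_report: bool = False):
    """Convert a normalized relative dose to absolute mGy/100 mAs:

    D_abs = rel * [CTDI100(avg isocenter depth) / rel(isocenter)]
                * (mAs_per_rotation / 100)
    """
    if rel.kind != "relative":
        raise ConfigurationError("calibrate_absolute expects a relative dose grid")
    options = options or EngineOptions()
    rel_iso = rel.point_value(spec.isocenter)
    if rel_iso <= 0.0:
        raise CalibrationError("relative dose at the isocenter is zero")
    z_ref = float(np.median(np.asarray(spec.slice_z_positions)))
    d_avg = average_isocenter_depth(density, spec.isocenter, z_ref,
                                    threshold=options.surface_threshold,
                                    step=options.depth_ray_step)
    ref = ctdi_reference(model.ctdi, d_avg)
    factor = ref / rel_iso * (spec.mAs_per_rotation / 100.0)
    log.info("calibration: avg depth %.2f mm, CTDI ref %.3f mGy/100mAs, "
             "rel(iso) %.5f, factor %.4f", d_avg, ref, rel_iso, factor)
    dose = DoseGrid(values=rel.values * factor, spacing=rel.spacing,
                    origin=rel.origin, kind="absolute", sigma=rel.sigma)
    if return_report:
        return dose, CalibrationReport(d_avg, ref, rel_iso, factor)
    return dose
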