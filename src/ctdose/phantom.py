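"""Voxel phantoms: grid container, HU -> electron-density conversion,
synthetic phantom/marker generation, and MetaImage / DICOM I/O.

Conventions: scanner-fixed right-handed frame with z along the rotation
axis; arrays are indexed ``[ix, iy, iz]``; voxels are cell-centered and
``origin`` is the world position of the center of voxel (0, 0, 0).  The
default working resolution is 1 x 1 x 4 mm3.  Anterior is -y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .beam_model import HUDensityCurve, default_hu_density_curve, hu_to_density_value
from .errors import ConfigurationError, DomainError, FormatError

log = logging.getLogger(__name__)

AIR_HU = -1000.0
DEFAULT_SPACING = (1.0, 1.0, 4.0)


@dataclass
class VoxelGrid:
    """3-D scalar volume (HU or relative electron density) with geometry."""

    values: np.ndarray  # (nx, ny, nz)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    value_kind: str = "hounsfield"  # "hounsfield" | "density"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.ndim != 3:
            raise ConfigurationError("VoxelGrid values must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be strictly positive")
        if self.value_kind == "density" and np.any(self.values < 0):
            raise ConfigurationError("density values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, point) -> np.ndarray:
        """Continuous (fractional) index of a world point."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Low/high corners of the grid box (half a voxel beyond centers)."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        return o - 0.5 * sp, o + (n - 0.5) * sp

    def contains_point(self, point) -> bool:
        lo, hi = self.bounds()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])


@dataclass
class MarkerSet:
    """Labeled voxel clusters standing in for the five TLD chips per site."""

    markers: dict[str, np.ndarray]  # label -> (n, 3) int indices

    def __post_init__(self):
        self.markers = {str(k): np.atleast_2d(np.asarray(v, dtype=np.intp))
                        for k, v in self.markers.items()}

    def labels(self) -> list[str]:
        return list(self.markers)

    def validate(self, grid: VoxelGrid) -> None:
        shape = np.asarray(grid.shape)
        for label, idx in self.markers.items():
            if idx.size == 0:
                raise ConfigurationError(f"marker {label!r} has an empty cluster")
            if np.any(idx < 0) or np.any(idx >= shape):
                raise ConfigurationError(f"marker {label!r} has out-of-range indices")


# ---------------------------------------------------------------------------
# HU -> density


def hu_to_density(grid: VoxelGrid, curve: HUDensityCurve | None = None) -> VoxelGrid:
    """Per-voxel piecewise-linear HU -> relative electron density.

    HU below the curve minimum are clamped to the first density point (a
    debug record is logged); geometry metadata is unchanged.
    """
    if grid.value_kind != "hounsfield":
        raise ConfigurationError(f"expected a hounsfield grid, got {grid.value_kind!r}")
    curve = curve or default_hu_density_curve()
    below = int(np.count_nonzero(grid.values < curve.hu_points[0]))
    if below:
        log.debug("hu_to_density: clamped %d voxels below HU %.0f",
                  below, curve.hu_points[0])
    dens = hu_to_density_value(curve, grid.values.astype(float))
    return VoxelGrid(values=dens, spacing=grid.spacing, origin=grid.origin,
                     value_kind="density")


# ---------------------------------------------------------------------------
# synthetic phantoms


def _centered_grid(extent_xy: tuple[float, float], length: float,
                   spacing, margin: float) -> VoxelGrid:
    """Empty (air) grid with odd in-plane voxel counts so the world origin
    falls on a voxel center (keeps rotational-symmetry tests exact)."""
    dx, dy, dz = spacing
    nx = int(np.ceil((extent_xy[0] + 2 * margin) / dx)) | 1
    ny = int(np.ceil((extent_xy[1] + 2 * margin) / dy)) | 1
    nz = max(int(np.ceil(length / dz)), 1) | 1
    origin = (-(nx - 1) / 2.0 * dx, -(ny - 1) / 2.0 * dy, -(nz - 1) / 2.0 * dz)
    values = np.full((nx, ny, nz), AIR_HU, dtype=float)
    return VoxelGrid(values=values, spacing=spacing, origin=origin)


def _inplane_mask(grid: VoxelGrid, a: float, b: float,
                  center=(0.0, 0.0)) -> np.ndarray:
    """Center-in/out mask of an axis-aligned ellipse (semi-axes a, b)."""
    x = grid.axis_coords(0) - center[0]
    y = grid.axis_coords(1) - center[1]
    return ((x[:, None] / a) ** 2 + (y[None, :] / b) ** 2) <= 1.0


def make_elliptic_cylinder(a: float, b: float, length: float, hu: float,
                           spacing=DEFAULT_SPACING, margin: float = 10.0) -> VoxelGrid:
    """Homogeneous elliptic cylinder (semi-axes a, b mm) along z, centered."""
    if a <= 0 or b <= 0 or length <= 0:
        raise ConfigurationError("semi-axes and length must be positive")
    if 2 * a < 2 * spacing[0] or 2 * b < 2 * spacing[1]:
        raise ConfigurationError("cylinder thinner than two voxels")
    grid = _centered_grid((2 * a, 2 * b), length, spacing, margin)
    mask = _inplane_mask(grid, a, b)
    zmask = np.abs(grid.axis_coords(2)) <= length / 2.0
    plane = np.where(mask, hu, AIR_HU)
    grid.values[:, :, zmask] = plane[:, :, None]
    return grid


def make_cylinder(diameter: float, length: float, hu: float,
                  spacing=DEFAULT_SPACING, margin: float = 10.0) -> VoxelGrid:
    """Circular cylinder along z through the grid center; voxels are
    assigned by the center-in/out rule (no anti-aliasing)."""
    return make_elliptic_cylinder(diameter / 2.0, diameter / 2.0, length, hu,
                                  spacing=spacing, margin=margin)


@dataclass
class ChestParams:
    """Geometry of the synthetic chest slab phantom.

    Presets emulate the thoracic cross-sections of a newborn and of a
    12-year-old child; all HU values are arbitrary tissue-equivalent
    choices and are documented, not measured.
    """

    body_semi_axes: tuple[float, float] = (55.0, 45.0)  # lateral, AP (mm)
    length: float = 180.0
    tissue_hu: float = 30.0
    lung_hu: float = -700.0
    bone_hu: float = 700.0
    lung_frac: tuple[float, float] = (0.34, 0.52)  # semi-axes / body semi-axes
    lung_offset_frac: float = 0.44  # lateral lung-center offset / body a
    rib_frac: tuple[float, float] = (0.88, 0.97)  # ring inner/outer fraction
    gap_mm: float = 0.0  # inter-slab air-gap thickness; 0 disables
    gap_interval: float = 25.0  # mm between slab gaps
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    margin: float = 10.0


CHEST_PRESETS = {
    "newborn": ChestParams(),
    "child": ChestParams(body_semi_axes=(115.0, 85.0), length=300.0),
}

CHEST_MARKER_LABELS = ("Left Lung", "Right Lung", "Left Rib", "Right Rib",
                       "Sternum", "Left Breast", "Right Breast")


def make_chest_phantom(preset: str = "newborn",
                       params: ChestParams | None = None,
                       seed: int = 0) -> tuple[VoxelGrid, MarkerSet]:
    """Synthetic chest phantom plus TLD-site markers.

    Deterministic for fixed ``(params, seed)``.  ``gap_mm > 0`` inserts thin
    transverse air layers at regular z intervals, emulating the inter-slab
    air gaps of physical sectional phantoms.
    """
    if params is None:
        try:
            params = CHEST_PRESETS[preset]
        except KeyError:
            raise ConfigurationError(f"unknown chest preset {preset!r}") from None
    a, b = params.body_semi_axes
    la, lb = params.lung_frac[0] * a, params.lung_frac[1] * b
    if params.lung_offset_frac * a + la >= a:
        raise ConfigurationError("lungs exceed the body outline")

    grid = _centered_grid((2 * a, 2 * b), params.length, params.spacing,
                          params.margin)
    rng = np.random.default_rng(seed)
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    z = grid.axis_coords(2)
    half = params.length / 2.0
    zmask = np.abs(z) <= half

    body = _inplane_mask(grid, a, b)
    r2 = (x[:, None] / a) ** 2 + (y[None, :] / b) ** 2
    rib_ring = (r2 >= params.rib_frac[0] ** 2) & (r2 <= params.rib_frac[1] ** 2)
    lung_l = _inplane_mask(grid, la, lb, center=(params.lung_offset_frac * a, 0.0))
    lung_r = _inplane_mask(grid, la, lb, center=(-params.lung_offset_frac * a, 0.0))
    # small anterior sternum block
    sternum = (np.abs(x[:, None]) <= 0.08 * a) & \
        (y[None, :] <= -0.78 * b) & (y[None, :] >= -0.92 * b) & body

    plane = np.full((grid.shape[0], grid.shape[1]), AIR_HU)
    plane[body] = params.tissue_hu
    plane[rib_ring & body] = params.bone_hu
    plane[(lung_l | lung_r) & body] = params.lung_hu
    plane[sternum] = params.bone_hu
    grid.values[:, :, zmask] = plane[:, :, None]

    k_mid = grid.shape[2] // 2

    def _anchor(xw: float, yw: float, mask: np.ndarray, label: str) -> np.ndarray:
        i0 = int(round((xw - grid.origin[0]) / grid.spacing[0]))
        j0 = int(round((yw - grid.origin[1]) / grid.spacing[1]))
        # deterministic jitter, then snap to the nearest in-structure voxel
        i0 += int(rng.integers(-1, 2))
        j0 += int(rng.integers(-1, 2))
        if not mask[i0, j0]:
            ii, jj = np.nonzero(mask)
            d2 = (ii - i0) ** 2 + (jj - j0) ** 2
            best = int(np.argmin(d2))
            i0, j0 = int(ii[best]), int(jj[best])
        cluster = [(i0, j0, k_mid)]
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            i1, j1 = i0 + di, j0 + dj
            if mask[i1, j1]:
                cluster.append((i1, j1, k_mid))
        return np.array(cluster[:5], dtype=np.intp)

    markers = MarkerSet(markers={
        "Left Lung": _anchor(params.lung_offset_frac * a, 0.0, lung_l & body, "Left Lung"),
        "Right Lung": _anchor(-params.lung_offset_frac * a, 0.0, lung_r & body, "Right Lung"),
        "Left Rib": _anchor(0.925 * a, 0.0, rib_ring & body, "Left Rib"),
        "Right Rib": _anchor(-0.925 * a, 0.0, rib_ring & body, "Right Rib"),
        "Sternum": _anchor(0.0, -0.85 * b, sternum, "Sternum"),
        "Left Breast": _anchor(0.30 * a, -0.80 * b,
                               body & ~rib_ring & ~lung_l & ~lung_r & ~sternum,
                               "Left Breast"),
        "Right Breast": _anchor(-0.30 * a, -0.80 * b,
                                body & ~rib_ring & ~lung_l & ~lung_r & ~sternum,
                                "Right Breast"),
    })

    if params.gap_mm > 0:
        _insert_air_gaps(grid, params.gap_interval, params.gap_mm,
                         protect_k=k_mid)
    markers.validate(grid)
    return grid, markers


@dataclass
class HeadParams:
    body_semi_axes: tuple[float, float] = (60.0, 75.0)
    length: float = 140.0
    tissue_hu: float = 40.0
    bone_hu: float = 900.0
    skull_frac: tuple[float, float] = (0.88, 0.98)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    margin: float = 10.0


HEAD_PRESETS = {
    "newborn": HeadParams(body_semi_axes=(45.0, 55.0), length=110.0),
    "child": HeadParams(),
}

HEAD_MARKER_LABELS = ("Skull", "Left Eye", "Right Eye", "Jaw")


def make_head_phantom(preset: str = "child",
                      params: HeadParams | None = None,
                      seed: int = 0) -> tuple[VoxelGrid, MarkerSet]:
    """Simple elliptic head phantom: brain tissue inside a skull shell,
    with skull / eye / jaw marker sites."""
    if params is None:
        try:
            params = HEAD_PRESETS[preset]
        except KeyError:
            raise ConfigurationError(f"unknown head preset {preset!r}") from None
    a, b = params.body_semi_axes
    grid = _centered_grid((2 * a, 2 * b), params.length, params.spacing,
                          params.margin)
    rng = np.random.default_rng(seed)
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    z = grid.axis_coords(2)
    zmask = np.abs(z) <= params.length / 2.0

    body = _inplane_mask(grid, a, b)
    r2 = (x[:, None] / a) ** 2 + (y[None, :] / b) ** 2
    shell = (r2 >= params.skull_frac[0] ** 2) & (r2 <= params.skull_frac[1] ** 2)
    plane = np.full((grid.shape[0], grid.shape[1]), AIR_HU)
    plane[body] = params.tissue_hu
    plane[shell & body] = params.bone_hu
    grid.values[:, :, zmask] = plane[:, :, None]

    k_mid = grid.shape[2] // 2
    interior = body & ~shell

    def _cluster(xw, yw, mask):
        i0 = int(round((xw - grid.origin[0]) / grid.spacing[0]))
        j0 = int(round((yw - grid.origin[1]) / grid.spacing[1]))
        i0 += int(rng.integers(-1, 2))
        j0 += int(rng.integers(-1, 2))
        if not mask[i0, j0]:
            ii, jj = np.nonzero(mask)
            best = int(np.argmin((ii - i0) ** 2 + (jj - j0) ** 2))
            i0, j0 = int(ii[best]), int(jj[best])
        cl = [(i0, j0, k_mid)]
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if mask[i0 + di, j0 + dj]:
                cl.append((i0 + di, j0 + dj, k_mid))
        return np.array(cl[:5], dtype=np.intp)

    markers = MarkerSet(markers={
        "Skull": _cluster(0.0, 0.93 * b, shell & body),
        "Left Eye": _cluster(0.40 * a, -0.70 * b, interior),
        "Right Eye": _cluster(-0.40 * a, -0.70 * b, interior),
        "Jaw": _cluster(0.0, -0.80 * b, interior),
    })
    markers.validate(grid)
    return grid, markers


def _insert_air_gaps(grid: VoxelGrid, interval: float, gap_mm: float,
                     protect_k: int | None = None) -> None:
    """Overwrite thin transverse layers with air every ``interval`` mm,
    skipping the slab that holds the markers."""
    dz = grid.spacing[2]
    n_layers = max(int(round(gap_mm / dz)), 1)
    step = max(int(round(interval / dz)), 2)
    for k0 in range(step, grid.shape[2] - 1, step):
        if protect_k is not None and abs(k0 - protect_k) <= n_layers:
            continue
        grid.values[:, :, k0:k0 + n_layers] = AIR_HU


# ---------------------------------------------------------------------------
# volume I/O (MetaImage via SimpleITK; DICOM series import)


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid as an uncompressed MetaImage (.mhd + .raw) pair."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        grid.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path, value_kind: str = "hounsfield") -> VoxelGrid:
    """Read a MetaImage volume back into a :class:`VoxelGrid`."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(values=arr, spacing=tuple(img.GetSpacing()),
                     origin=tuple(img.GetOrigin()), value_kind=value_kind)


def read_dicom_series(directory) -> VoxelGrid:
    """Import a DICOM CT series as an HU grid (rescale slope/intercept are
    applied by the reader; all other tags are discarded)."""
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FormatError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
    return VoxelGrid(values=arr, spacing=tuple(img.GetSpacing()),
                     origin=tuple(img.GetOrigin()), value_kind="hounsfield")


# ---------------------------------------------------------------------------
# marker CSV


def write_markers(markers: MarkerSet, path) -> None:
    rows = [(label, int(i), int(j), int(k))
            for label, idx in markers.markers.items()
            for i, j, k in idx]
    pd.DataFrame(rows, columns=["label", "i", "j", "k"]).to_csv(path, index=False)


def read_markers(path) -> MarkerSet:
    df = pd.read_csv(path)
    expected = ["label", "i", "j", "k"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    markers = {label: sub[["i", "j", "k"]].to_numpy(dtype=np.intp)
               for label, sub in df.groupby("label", sort=False)}
    return MarkerSet(markers=markers)
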