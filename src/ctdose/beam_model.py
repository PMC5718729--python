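"""Commissioning data for the semi-empirical CT dose engine.

A beam model bundles, for one technique (tube potential, bowtie filter,
nominal beam width), the four measured datasets the engine consumes:

* a tissue-maximum-ratio (TMR) curve — dose versus water-equivalent depth,
  normalized to 1 at the reference (maximum) depth;
* two crossbeam profiles measured free-in-air at the isocenter plane — one
  transaxial (across the fan, shaped by the bowtie filter) and one
  longitudinal (across the collimated slice, carrying the anode heel
  asymmetry) — each normalized at the center of its full width at half
  maximum (FWHM);
* a CTDI100 reference table: center dose per 100 mAs in standard PMMA
  cylinders, indexed by depth from isocenter to surface (cylinder radius),
  used as the absolute-calibration anchor.

The module also synthesizes physically plausible commissioning sets so the
whole toolchain can run without access to scanner measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CommissioningError, ConfigurationError, DomainError, FormatError

SUPPORTED_BEAM_WIDTHS = (5.0, 10.0, 15.0, 20.0)
BOWTIES = ("head", "body")

#: Fan half-width at the isocenter plane per bowtie (half the scan field of
#: view: 25 cm head, 50 cm body).
FAN_HALF_WIDTH_MM = {"head": 125.0, "body": 250.0}

#: Parametric bowtie: equivalent-aluminium thickness grows quadratically from
#: zero on the central ray to this value at the fan edge.
BOWTIE_AL_TMAX_MM = {"head": 10.0, "body": 14.0}

#: Effective linear attenuation of aluminium near the mean spectral energy of
#: a heavily filtered 120 kVp beam (~60 keV), used for the synthetic
#: transaxial profile; matches the packaged aluminium table at 60 keV so the
#: engine's bowtie shading and the Monte Carlo source model agree.
AL_MU_EFF_PER_MM = 0.0775

#: Default source-to-isocenter distance (mm); configurable everywhere.
DEFAULT_SID = 541.0


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TMRCurve:
    depths: np.ndarray  # mm, water-equivalent, strictly increasing from 0
    values: np.ndarray  # dimensionless, max 1.0 at the reference depth
    kvp: float = 120.0
    bowtie: str = "head"
    beam_width: float = 10.0


@dataclass(frozen=True)
class CrossProfile:
    axis: str  # "transaxial_x" | "longitudinal_z"
    offsets: np.ndarray  # mm at the isocenter plane
    values: np.ndarray  # relative dose in (0, 1]
    kvp: float = 120.0
    bowtie: str = "head"
    beam_width: float = 10.0


@dataclass(frozen=True)
class CTDITable:
    diameters: np.ndarray  # mm
    center_dose: np.ndarray  # mGy / 100 mAs at the cylinder center
    kvp: float = 120.0
    bowtie: str = "head"
    beam_width: float = 10.0

    @property
    def depths(self) -> np.ndarray:
        """Depth from isocenter to surface = cylinder radius."""
        return self.diameters / 2.0


@dataclass(frozen=True)
class HUDensityCurve:
    hu_points: np.ndarray
    density_points: np.ndarray  # relative electron density


@dataclass(frozen=True)
class BeamModel:
    tmr: TMRCurve
    profile_x: CrossProfile
    profile_z: CrossProfile
    ctdi: CTDITable
    source_to_isocenter: float = DEFAULT_SID
    kvp: float = 120.0
    bowtie: str = "head"
    beam_width: float = 10.0


def default_hu_density_curve() -> HUDensityCurve:
    """Piecewise-linear HU -> relative electron density conversion.

    Anchored at air (-1000 HU -> 0) and water (0 HU -> 1); the bone branch
    has the usual shallower slope (1000 HU -> ~1.55).
    """
    return HUDensityCurve(
        hu_points=np.array([-1000.0, 0.0, 1000.0, 3000.0]),
        density_points=np.array([0.0, 1.0, 1.55, 2.5]),
    )


# ---------------------------------------------------------------------------
# validation


def _as1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def validate_tmr(curve: TMRCurve) -> None:
    d, v = _as1d(curve.depths), _as1d(curve.values)
    if d.size < 2 or d.size != v.size:
        raise CommissioningError("TMR curve needs >= 2 matching (depth, value) pairs")
    if d[0] != 0.0:
        raise CommissioningError("TMR depths must start at 0")
    if np.any(np.diff(d) <= 0):
        raise CommissioningError("TMR depths must be strictly increasing")
    if np.any(v <= 0):
        raise CommissioningError("TMR values must be strictly positive")
    if abs(v.max() - 1.0) > 1e-9:
        raise CommissioningError("TMR must be normalized to 1.0 at the reference depth")
    imax = int(np.argmax(v))
    if np.any(np.diff(v[imax:]) > 1e-12):
        raise CommissioningError("TMR must be non-increasing beyond the buildup region")


def validate_profile(profile: CrossProfile) -> None:
    o, v = _as1d(profile.offsets), _as1d(profile.values)
    if profile.axis not in ("transaxial_x", "longitudinal_z"):
        raise CommissioningError(f"unknown profile axis {profile.axis!r}")
    if o.size < 3 or o.size != v.size:
        raise CommissioningError("profile needs >= 3 matching (offset, value) pairs")
    if np.any(np.diff(o) <= 0):
        raise CommissioningError("profile offsets must be strictly increasing")
    if np.any(v <= 0) or np.any(v > 1.0 + 1e-9):
        raise CommissioningError("profile values must lie in (0, 1]")
    c, _ = fwhm_center(profile)  # raises if half-max never crossed
    if not (o[0] < c < o[-1]):
        raise CommissioningError("FWHM center outside the measured offsets")


def validate_ctdi(table: CTDITable) -> None:
    d, v = _as1d(table.diameters), _as1d(table.center_dose)
    if d.size == 0:
        raise ConfigurationError("empty CTDI reference table")
    if d.size != v.size:
        raise CommissioningError("CTDI table columns differ in length")
    if np.any(np.diff(d) <= 0):
        raise CommissioningError("CTDI diameters must be strictly increasing")
    if np.any(v <= 0):
        raise CommissioningError("CTDI center doses must be strictly positive")
    if np.any(np.diff(v) > 1e-12):
        raise CommissioningError("CTDI center dose must be non-increasing with diameter")


def validate_hu_curve(curve: HUDensityCurve) -> None:
    h, r = _as1d(curve.hu_points), _as1d(curve.density_points)
    if h.size < 2 or h.size != r.size:
        raise CommissioningError("HU curve needs >= 2 matching points")
    if np.any(np.diff(h) <= 0):
        raise CommissioningError("HU points must be strictly increasing")
    if np.any(np.diff(r) < 0) or np.any(r < 0):
        raise CommissioningError("density points must be non-negative and non-decreasing")


def validate_beam_model(model: BeamModel) -> None:
    validate_tmr(model.tmr)
    validate_profile(model.profile_x)
    validate_profile(model.profile_z)
    validate_ctdi(model.ctdi)
    if model.source_to_isocenter <= 0:
        raise CommissioningError("source_to_isocenter must be positive")
    key = (model.kvp, model.bowtie, model.beam_width)
    for part in (model.tmr, model.profile_x, model.profile_z, model.ctdi):
        if (part.kvp, part.bowtie, part.beam_width) != key:
            raise CommissioningError(
                "beam-model components carry inconsistent (kvp, bowtie, beam_width)"
            )
    if model.beam_width not in SUPPORTED_BEAM_WIDTHS:
        raise CommissioningError(
            f"beam width {model.beam_width} mm not in the commissioning set "
            f"{SUPPORTED_BEAM_WIDTHS}"
        )


# ---------------------------------------------------------------------------
# operations


def interp_tmr(curve: TMRCurve, depth: float) -> float:
    """TMR at an arbitrary water-equivalent depth (mm).

    Linear between table nodes; beyond the last node the curve is continued
    exponentially with the log-slope of the final table segment (kilovoltage
    depth dose is near-exponential at depth).
    """
    if depth < 0:
        raise DomainError(f"negative depth {depth}")
    d = _as1d(curve.depths)
    v = _as1d(curve.values)
    if depth <= d[-1]:
        return float(np.interp(depth, d, v))
    return float(v[-1] * math.exp(-tmr_tail_mu(curve) * (depth - d[-1])))


def tmr_tail_mu(curve: TMRCurve) -> float:
    """Log-slope of the final TMR segment (per mm), used for extrapolation."""
    d = _as1d(curve.depths)
    v = _as1d(curve.values)
    if v[-1] >= v[-2]:
        return 0.0
    return float((math.log(v[-2]) - math.log(v[-1])) / (d[-1] - d[-2]))


def fwhm_center(profile: CrossProfile) -> tuple[float, float]:
    """Locate the profile center as the midpoint of the two half-maximum
    crossings (linear interpolation between bracketing samples).

    Returns ``(center, fwhm)``.
    """
    o = _as1d(profile.offsets)
    v = _as1d(profile.values)
    half = v.max() / 2.0
    imax = int(np.argmax(v))
    # left crossing: last upward crossing before the maximum
    left = None
    for i in range(imax, 0, -1):
        if v[i - 1] < half <= v[i]:
            w = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = o[i - 1] + w * (o[i] - o[i - 1])
            break
    right = None
    for i in range(imax, o.size - 1):
        if v[i] >= half > v[i + 1]:
            w = (v[i] - half) / (v[i] - v[i + 1])
            right = o[i] + w * (o[i + 1] - o[i])
            break
    if left is None or right is None:
        raise CommissioningError(
            "profile never falls below half-maximum on "
            + ("both sides" if left is None and right is None
               else "the left side" if left is None else "the right side")
        )
    return (0.5 * (left + right), right - left)


def normalize_profile(profile: CrossProfile) -> CrossProfile:
    """Normalize at the FWHM center: divide by the interpolated value there
    and re-express offsets relative to the center."""
    center, _ = fwhm_center(profile)
    o = _as1d(profile.offsets)
    v = _as1d(profile.values)
    vc = float(np.interp(center, o, v))
    return replace(profile, offsets=o - center, values=v / vc)


class CTDIRangeWarning(UserWarning):
    """Requested depth outside the CTDI reference table; value clamped."""


def ctdi_reference(table: CTDITable, depth: float) -> float:
    """CTDI100 center dose (mGy/100 mAs) at a given isocenter-to-surface
    depth, by linear interpolation in depth (= cylinder radius).

    Outside the covered range the nearest entry is used and a
    :class:`CTDIRangeWarning` is emitted.
    """
    d = _as1d(table.diameters)
    if d.size == 0:
        raise ConfigurationError("empty CTDI reference table")
    if depth <= 0:
        raise DomainError(f"depth must be positive, got {depth}")
    depths = d / 2.0
    v = _as1d(table.center_dose)
    if depth < depths[0] or depth > depths[-1]:
        warnings.warn(
            f"depth {depth:.1f} mm outside CTDI table range "
            f"[{depths[0]:.1f}, {depths[-1]:.1f}] mm; clamping",
            CTDIRangeWarning,
            stacklevel=2,
        )
    return float(np.interp(depth, depths, v))


def hu_to_density_value(curve: HUDensityCurve, hu) -> np.ndarray:
    """Scalar/array HU -> relative electron density (clamped at the ends)."""
    return np.interp(hu, _as1d(curve.hu_points), _as1d(curve.density_points))


# ---------------------------------------------------------------------------
# synthetic commissioning data


def bowtie_al_thickness(fan_angle: float, bowtie: str,
                        sid: float = DEFAULT_SID) -> float:
    """Equivalent-aluminium bowtie thickness (mm) at a fan angle (rad).

    Quadratic from zero on the central ray to the bowtie's maximum at the
    edge of the fan; the real filter geometry is proprietary, so this
    parametric stand-in is shared by the dose engine's synthetic transaxial
    profile and the Monte Carlo source model.
    """
    phi_max = math.atan(FAN_HALF_WIDTH_MM[bowtie] / sid)
    frac = min(abs(fan_angle) / phi_max, 1.5)
    return BOWTIE_AL_TMAX_MM[bowtie] * frac * frac


@dataclass
class SyntheticBeamParams:
    """Knobs for the synthetic commissioning generator.

    Defaults emulate a heavily filtered 120 kVp fan beam: broad-beam
    effective attenuation 0.0185/mm in water (HVL ~ 37 mm), a quadratic
    equivalent-aluminium bowtie, a near-rectangular longitudinal profile
    with ~1.5 mm penumbra, and an anode heel expressed as asymmetric
    shoulder widths.
    """

    kvp: float = 120.0
    bowtie: str = "head"
    beam_width: float = 10.0
    mu_eff: float = 0.0185  # per mm water, broad-beam
    heel_tilt: float = 0.25  # 0 -> symmetric longitudinal profile
    penumbra: float = 1.5  # mm
    sid: float = DEFAULT_SID
    tmr_max_depth: float = 350.0
    tmr_step: float = 5.0
    ctdi_anchors: Mapping[float, float] | None = None  # diameter mm -> mGy/100mAs
    noise_sd: float = 0.0  # relative measurement jitter; 0 = clean curves
    tmr_override: tuple[Sequence[float], Sequence[float]] | None = None

    def resolved_ctdi(self) -> dict[float, float]:
        if self.ctdi_anchors is not None:
            return dict(self.ctdi_anchors)
        if self.bowtie == "head":
            return {100.0: 32.0, 160.0: 25.0, 240.0: 16.5, 320.0: 10.5}
        return {100.0: 28.0, 160.0: 21.0, 240.0: 13.5, 320.0: 8.5}


def generate_synthetic_beam_model(params: SyntheticBeamParams | None = None,
                                  seed: int = 0) -> BeamModel:
    """Deterministically synthesize a full commissioning set.

    The output always satisfies every beam-model invariant (profiles are
    normalized at their FWHM center and clipped at unity; the TMR is
    monotone beyond buildup).
    """
    p = params or SyntheticBeamParams()
    if p.mu_eff <= 0:
        raise ConfigurationError(f"non-physical attenuation mu_eff={p.mu_eff}")
    if p.penumbra <= 0:
        raise ConfigurationError("penumbra must be positive")
    if p.bowtie not in BOWTIES:
        raise ConfigurationError(f"unknown bowtie {p.bowtie!r}")
    rng = np.random.default_rng(seed)
    key = dict(kvp=p.kvp, bowtie=p.bowtie, beam_width=p.beam_width)

    # --- TMR ---------------------------------------------------------------
    if p.tmr_override is not None:
        td = _as1d(p.tmr_override[0])
        tv = _as1d(p.tmr_override[1])
    else:
        td = np.arange(0.0, p.tmr_max_depth + 0.5 * p.tmr_step, p.tmr_step)
        tv = np.exp(-p.mu_eff * td)
    if p.noise_sd > 0:
        tv = tv * (1.0 + p.noise_sd * rng.standard_normal(tv.size))
    tv = np.minimum.accumulate(np.clip(tv, 1e-9, None))
    tv = tv / tv.max()
    tmr = TMRCurve(depths=td, values=tv, **key)

    # --- transaxial profile: bowtie transmission with a penumbral edge -----
    fan = FAN_HALF_WIDTH_MM[p.bowtie]
    edge_pad = 6.0 * p.penumbra
    xo = np.linspace(-(fan + edge_pad), fan + edge_pad, 181)
    phi = np.arctan(xo / p.sid)
    t_al = np.array([bowtie_al_thickness(a, p.bowtie, p.sid) for a in phi])
    vx = np.exp(-AL_MU_EFF_PER_MM * t_al)
    # roll off smoothly beyond the fan edge (collimator shadow)
    vx = vx * 0.5 * (1.0 + _erf_vec((fan - np.abs(xo)) / p.penumbra))
    profile_x = _finish_profile("transaxial_x", xo, vx, rng, p.noise_sd, key)

    # --- longitudinal profile: near-rectangle, heel as asymmetric widths ---
    hw = p.beam_width / 2.0
    zo = np.linspace(-(hw + 8.0 * p.penumbra), hw + 8.0 * p.penumbra, 161)
    w_minus = p.penumbra * (1.0 + p.heel_tilt)  # anode side falls off slower
    w_plus = p.penumbra * max(1.0 - 0.5 * p.heel_tilt, 0.2)
    vz = 0.5 * (_erf_vec((zo + hw) / w_minus) - _erf_vec((zo - hw) / w_plus))
    profile_z = _finish_profile("longitudinal_z", zo, vz, rng, p.noise_sd, key)

    # --- CTDI reference table ----------------------------------------------
    anchors = p.resolved_ctdi()
    dia = np.array(sorted(anchors))
    dose = np.array([anchors[d] for d in dia])
    if p.noise_sd > 0:
        dose = dose * (1.0 + 0.5 * p.noise_sd * rng.standard_normal(dose.size))
        dose = np.minimum.accumulate(dose)
    ctdi = CTDITable(diameters=dia, center_dose=dose, **key)

    model = BeamModel(tmr=tmr, profile_x=profile_x, profile_z=profile_z,
                      ctdi=ctdi, source_to_isocenter=p.sid, **key)
    validate_beam_model(model)
    return model


def _erf_vec(x: np.ndarray) -> np.ndarray:
    return np.array([math.erf(v) for v in np.asarray(x, dtype=float).ravel()])


def _finish_profile(axis, offsets, values, rng, noise_sd, key) -> CrossProfile:
    if noise_sd > 0:
        values = values * (1.0 + noise_sd * rng.standard_normal(values.size))
    values = np.clip(values, 1e-6, None)
    prof = normalize_profile(CrossProfile(axis=axis, offsets=offsets,
                                          values=values, **key))
    # normalization is at the FWHM center, not the max: clip the residual
    # sliver above unity so the stored profile satisfies the (0, 1] contract
    return replace(prof, values=np.clip(prof.values, 1e-6, 1.0))


# ---------------------------------------------------------------------------
# commissioning CSV dialect
#
# UTF-8; '#'-prefixed "key=value" metadata lines, then "abscissa,value" rows.
# One file per curve; a manifest lists the four files of a BeamModel.

_KIND_COLUMNS = {
    "tmr": ("depth_mm", "tmr"),
    "profile": ("offset_mm", "value"),
    "ctdi": ("diameter_mm", "center_dose_mGy_per_100mAs"),
    "hu_density": ("hu", "relative_electron_density"),
}


def write_commissioning_csv(path, kind: str, meta: Mapping[str, object],
                            abscissa: Iterable[float],
                            values: Iterable[float]) -> None:
    cols = _KIND_COLUMNS[kind]
    lines = [f"# kind={kind}"]
    lines += [f"# {k}={v}" for k, v in meta.items()]
    lines.append(",".join(cols))
    lines += [f"{a:.9g},{v:.9g}" for a, v in zip(abscissa, values, strict=True)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_commissioning_csv(path) -> tuple[str, dict, np.ndarray, np.ndarray]:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    header_seen = False
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            header_seen = True  # column-name row
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: expected two columns, got {line!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric row {line!r}") from exc
    kind = meta.pop("kind", None)
    if kind is None:
        raise FormatError(f"{path}: missing '# kind=' metadata line")
    return kind, meta, np.array(xs), np.array(ys)


def _meta_key(meta: Mapping[str, str]) -> dict:
    return dict(kvp=float(meta["kvp"]), bowtie=meta["bowtie"],
                beam_width=float(meta["beam_width"]))


def save_beam_model(model: BeamModel, outdir) -> Path:
    """Write the four commissioning CSVs plus a manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(kvp=model.kvp, bowtie=model.bowtie, beam_width=model.beam_width)
    write_commissioning_csv(outdir / "tmr.csv", "tmr", meta,
                            model.tmr.depths, model.tmr.values)
    for name, prof in (("profile_x", model.profile_x),
                       ("profile_z", model.profile_z)):
        write_commissioning_csv(outdir / f"{name}.csv", "profile",
                                {**meta, "axis": prof.axis},
                                prof.offsets, prof.values)
    write_commissioning_csv(outdir / "ctdi.csv", "ctdi", meta,
                            model.ctdi.diameters, model.ctdi.center_dose)
    manifest = outdir / "model.manifest"
    manifest.write_text(
        "\n".join([
            f"# kvp={model.kvp}",
            f"# bowtie={model.bowtie}",
            f"# beam_width={model.beam_width}",
            f"# source_to_isocenter={model.source_to_isocenter}",
            "tmr=tmr.csv",
            "profile_x=profile_x.csv",
            "profile_z=profile_z.csv",
            "ctdi=ctdi.csv",
        ]) + "\n",
        encoding="utf-8",
    )
    return manifest


def load_beam_model(manifest_path, validate: bool = True) -> BeamModel:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    meta: dict[str, str] = {}
    files: dict[str, str] = {}
    for raw in manifest_path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        elif "=" in line:
            k, v = line.split("=", 1)
            files[k.strip()] = v.strip()
    missing = {"tmr", "profile_x", "profile_z", "ctdi"} - set(files)
    if missing:
        raise FormatError(f"{manifest_path}: manifest missing entries {sorted(missing)}")

    parts = {}
    for role in ("tmr", "profile_x", "profile_z", "ctdi"):
        kind, fmeta, xs, ys = read_commissioning_csv(base / files[role])
        key = _meta_key(fmeta)
        if role == "tmr":
            parts[role] = TMRCurve(depths=xs, values=ys, **key)
        elif role == "ctdi":
            parts[role] = CTDITable(diameters=xs, center_dose=ys, **key)
        else:
            parts[role] = CrossProfile(axis=fmeta.get("axis", "transaxial_x"),
                                       offsets=xs, values=ys, **key)
    model = BeamModel(
        tmr=parts["tmr"], profile_x=parts["profile_x"],
        profile_z=parts["profile_z"], ctdi=parts["ctdi"],
        source_to_isocenter=float(meta.get("source_to_isocenter", DEFAULT_SID)),
        kvp=float(meta["kvp"]), bowtie=meta["bowtie"],
        beam_width=float(meta["beam_width"]),
    )
    if validate:
        validate_beam_model(model)
    return model
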