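"""Simplified kilovoltage photon Monte Carlo dose cross-check.

An independent check of the semi-empirical engine: photons are sampled
from a packaged 120 kVp spectrum, emitted from rotating fan-collimated
source positions (bowtie modeled as equivalent-aluminium thickness versus
fan angle), and transported voxel-to-voxel with photoelectric, Compton
(Klein-Nishina) and Rayleigh interaction sampling.  Energy transferred to
electrons is deposited locally (kerma approximation: secondary-electron
ranges at <= 120 keV are sub-voxel at millimetre resolution), and photons
falling below a 1 keV cutoff are absorbed on the spot.  Per-voxel
uncertainty is accumulated history by history.

Materials are assigned from relative electron density bands
(air / lung / soft tissue / bone); cross-sections come from packaged
parametric tables (see ``data/materials_mu.csv``).  The random stream is a
seeded xorshift128+ generator, so a fixed ``(seed, n_histories)`` pair is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .beam_model import BOWTIE_AL_TMAX_MM, FAN_HALF_WIDTH_MM, BeamModel
from .dose_engine import DoseGrid, ScanSpec, _require_commissioned, _require_density
from .errors import ConfigurationError, DomainError
from .phantom import VoxelGrid

MEC2_KEV = 511.0
RNG_NAME = "xorshift128+"

#: relative-electron-density band edges for material assignment
DENSITY_BANDS = (0.05, 0.60, 1.10)  # air | lung | soft tissue | bone
MATERIAL_NAMES = ("air", "lung", "soft_tissue", "bone")
#: nominal mass density per unit relative electron density (g/cm3)
MASS_PER_EDENSITY = (1.09, 1.00, 1.00, 1.19)
AL_DENSITY = 2.699  # g/cm3


# ---------------------------------------------------------------------------
# packaged data


@dataclass(frozen=True)
class Spectrum:
    energies: np.ndarray  # keV, increasing
    weights: np.ndarray  # relative fluence, normalized to sum 1
    kvp: float = 120.0

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ConfigurationError("spectrum energies must increase")
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("spectrum weights must be non-negative")
        if e.max() > self.kvp + 1e-9:
            raise ConfigurationError("spectrum extends beyond the tube potential")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / w.sum())

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)


@dataclass(frozen=True)
class MaterialTables:
    """Mass attenuation coefficients (cm^2/g) per material and process on a
    common energy grid; interpolation is log-log."""

    energies: np.ndarray  # keV
    photoelectric: dict[str, np.ndarray]
    compton: dict[str, np.ndarray]
    rayleigh: dict[str, np.ndarray]

    def materials(self) -> list[str]:
        return list(self.photoelectric)

    def mu_rho(self, material: str, energy_keV, process: str = "total"):
        comp = {
            "photoelectric": self.photoelectric,
            "compton": self.compton,
            "rayleigh": self.rayleigh,
        }
        loge = np.log(np.asarray(energy_keV, dtype=float))
        lg = np.log(self.energies)
        if process == "total":
            tot = (self.photoelectric[material] + self.compton[material]
                   + self.rayleigh[material])
            return np.exp(np.interp(loge, lg, np.log(tot)))
        return np.exp(np.interp(loge, lg, np.log(comp[process][material])))


def _data_path(name: str) -> Path:
    return Path(resources.files("ctdose") / "data" / name)


def load_spectrum(path=None) -> Spectrum:
    df = pd.read_csv(path or _data_path("spectrum_120kvp.csv"), comment="#")
    return Spectrum(energies=df["energy_keV"].to_numpy(),
                    weights=df["weight"].to_numpy())


def load_material_tables(path=None) -> MaterialTables:
    df = pd.read_csv(path or _data_path("materials_mu.csv"), comment="#")
    pe, co, ra = {}, {}, {}
    energies = None
    for mat, sub in df.groupby("material", sort=False):
        sub = sub.sort_values("energy_keV")
        e = sub["energy_keV"].to_numpy()
        if energies is None:
            energies = e
        elif not np.allclose(e, energies):
            raise ConfigurationError("materials use different energy grids")
        pe[mat] = sub["mu_rho_photoelectric"].to_numpy()
        co[mat] = sub["mu_rho_compton"].to_numpy()
        ra[mat] = sub["mu_rho_rayleigh"].to_numpy()
    return MaterialTables(energies=energies, photoelectric=pe, compton=co,
                          rayleigh=ra)


# ---------------------------------------------------------------------------
# random stream (xorshift128+, splitmix64 seeding)


@njit(cache=True)
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _xs_rand(s0, s1):
    """Returns (u in [0,1), new_s0, new_s1)."""
    x = s0
    y = s1
    x = x ^ ((x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF))
    x = x ^ (x >> np.uint64(17))
    x = x ^ y ^ (y >> np.uint64(26))
    out = (x + y) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return np.float64(out) * 5.421010862427522e-20, y, x


def _seed_state(seed: int):
    s0 = np.uint64(_splitmix64(np.uint64(seed)))
    s1 = np.uint64(_splitmix64(s0))
    if s0 == 0 and s1 == 0:
        s1 = np.uint64(1)
    return s0, s1


# ---------------------------------------------------------------------------
# physics sampling


def compton_energy(energy_keV: float, angle_rad: float) -> float:
    """Scattered photon energy from the Compton relation."""
    return energy_keV / (1.0 + (energy_keV / MEC2_KEV)
                         * (1.0 - math.cos(angle_rad)))


@njit(cache=True)
def _kn_sample_one(e, s0, s1):
    """Sample the Klein-Nishina distribution at energy ``e`` (keV).

    Composition + rejection on eps = E'/E (standard kilovoltage scheme);
    returns (cos_theta, eps, s0, s1).
    """
    alpha = e / MEC2_KEV
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -math.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        u1, s0, s1 = _xs_rand(s0, s1)
        u2, s0, s1 = _xs_rand(s0, s1)
        u3, s0, s1 = _xs_rand(s0, s1)
        if u1 < a1 / (a1 + a2):
            eps = eps0 * math.exp(a1 * u2)
        else:
            eps = math.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * u2)
        t = (1.0 - eps) / (alpha * eps)
        sin2 = t * (2.0 - t)
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if u3 <= g:
            cost = 1.0 - t
            return cost, eps, s0, s1


@njit(cache=True)
def _kn_batch(e, n, s0, s1, cos_out, eps_out):
    for i in range(n):
        c, eps, s0, s1 = _kn_sample_one(e, s0, s1)
        cos_out[i] = c
        eps_out[i] = eps
    return s0, s1


def klein_nishina_sample(energy_keV: float, rng: np.random.Generator,
                         size: int | None = None):
    """Sample Compton scattering angles and scattered energies.

    Returns ``(theta, energy_prime)``; scalars when ``size`` is None.
    The stream is advanced by drawing a 64-bit seed from ``rng``.
    """
    n = 1 if size is None else int(size)
    s0, s1 = _seed_state(int(rng.integers(0, 2**63 - 1)))
    cos_out = np.empty(n)
    eps_out = np.empty(n)
    _kn_batch(float(energy_keV), n, s0, s1, cos_out, eps_out)
    theta = np.arccos(np.clip(cos_out, -1.0, 1.0))
    eprime = energy_keV * eps_out
    if size is None:
        return float(theta[0]), float(eprime[0])
    return theta, eprime


def sample_energy(spectrum: Spectrum, rng: np.random.Generator,
                  size: int | None = None):
    """Inverse-CDF draw from the spectrum (bin energies, discrete)."""
    u = rng.random(size)
    idx = np.searchsorted(spectrum.cdf(), u, side="right")
    idx = np.minimum(idx, spectrum.energies.size - 1)
    e = spectrum.energies[idx]
    return float(e) if size is None else e


# ---------------------------------------------------------------------------
# transport kernels


@njit(cache=True)
def _interp_loge(lg, arr, x):
    n = lg.shape[0]
    if x <= lg[0]:
        return arr[0]
    if x >= lg[n - 1]:
        return arr[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if lg[mid] <= x:
            lo = mid
        else:
            hi = mid
    w = (x - lg[lo]) / (lg[lo + 1] - lg[lo])
    return arr[lo] + w * (arr[lo + 1] - arr[lo])


@njit(cache=True)
def _deposit(sumd, sqd, tmp, last, idx, val, h):
    """History-by-history accumulation (flush-on-new-history)."""
    if last[idx] != h:
        prev = tmp[idx]
        if prev != 0.0:
            sumd[idx] += prev
            sqd[idx] += prev * prev
        tmp[idx] = val
        last[idx] = h
    else:
        tmp[idx] += val


@njit(cache=True)
def _rotate(ux, uy, uz, cost, phi):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0 else -1.0
        return sint * cosp, sign * sint * sinp, sign * cost
    den = math.sqrt(1.0 - uz * uz)
    vx = ux * cost + sint * (ux * uz * cosp - uy * sinp) / den
    vy = uy * cost + sint * (uy * uz * cosp + ux * sinp) / den
    vz = uz * cost - sint * den * cosp
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=True)
def _track(dens, matid, dx, dy, dz, lox, loy, loz,
           px, py, pz, ux, uy, uz, e, w, ecut,
           lg, mu_dens, p_pe, p_ray,
           sumd, sqd, tmp, last, h, s0, s1):
    """Transport one photon until absorption or escape, depositing
    transferred energy (kerma approximation) into the scoring arrays."""
    nx, ny, nz = dens.shape
    hx = lox + nx * dx
    hy = loy + ny * dy
    hz = loz + nz * dz
    while True:
        u, s0, s1 = _xs_rand(s0, s1)
        tau = -math.log(1.0 - u)
        # clip the semi-infinite ray to the grid box (distances, unit dir)
        t0 = 0.0
        t1 = 1e30
        miss = False
        for ax in range(3):
            if ax == 0:
                r, s, lo, hi = ux, px, lox, hx
            elif ax == 1:
                r, s, lo, hi = uy, py, loy, hy
            else:
                r, s, lo, hi = uz, pz, loz, hz
            if abs(r) < 1e-12:
                if s < lo or s > hi:
                    miss = True
                    break
            else:
                ta = (lo - s) / r
                tb = (hi - s) / r
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
        if miss or t0 >= t1:
            return s0, s1  # escapes without entering the grid
        tm = t0 + 1e-9 * (t1 - t0 + 1.0)
        i = int(math.floor((px + tm * ux - lox) / dx))
        j = int(math.floor((py + tm * uy - loy) / dy))
        k = int(math.floor((pz + tm * uz - loz) / dz))
        if i < 0:
            i = 0
        if i > nx - 1:
            i = nx - 1
        if j < 0:
            j = 0
        if j > ny - 1:
            j = ny - 1
        if k < 0:
            k = 0
        if k > nz - 1:
            k = nz - 1
        big = 1e30
        if abs(ux) > 1e-12:
            si = 1 if ux > 0 else -1
            tmx = ((lox + (i + (1 if ux > 0 else 0)) * dx) - px) / ux
            tdx = dx / abs(ux)
        else:
            si = 0
            tmx = big
            tdx = big
        if abs(uy) > 1e-12:
            sj = 1 if uy > 0 else -1
            tmy = ((loy + (j + (1 if uy > 0 else 0)) * dy) - py) / uy
            tdy = dy / abs(uy)
        else:
            sj = 0
            tmy = big
            tdy = big
        if abs(uz) > 1e-12:
            sk = 1 if uz > 0 else -1
            tmz = ((loz + (k + (1 if uz > 0 else 0)) * dz) - pz) / uz
            tdz = dz / abs(uz)
        else:
            sk = 0
            tmz = big
            tdz = big

        loge = math.log(e)
        acc = 0.0
        t = t0
        interacted = False
        while t < t1 - 1e-12:
            tn = tmx
            axis = 0
            if tmy < tn:
                tn = tmy
                axis = 1
            if tmz < tn:
                tn = tmz
                axis = 2
            if tn > t1:
                tn = t1
                axis = -1
            m = matid[i, j, k]
            mu = _interp_loge(lg, mu_dens[m], loge) * dens[i, j, k]
            seg = tn - t
            if mu > 0.0 and acc + mu * seg >= tau:
                t_int = t + (tau - acc) / mu
                px += t_int * ux
                py += t_int * uy
                pz += t_int * uz
                interacted = True
                break
            acc += mu * seg
            t = tn
            if axis == 0:
                i += si
                tmx += tdx
                if i < 0 or i >= nx:
                    break
            elif axis == 1:
                j += sj
                tmy += tdy
                if j < 0 or j >= ny:
                    break
            elif axis == 2:
                k += sk
                tmz += tdz
                if k < 0 or k >= nz:
                    break
            else:
                break
        if not interacted:
            return s0, s1  # escaped through the far side

        idx = (i * ny + j) * nz + k
        m = matid[i, j, k]
        ppe = _interp_loge(lg, p_pe[m], loge)
        pray = _interp_loge(lg, p_ray[m], loge)
        u, s0, s1 = _xs_rand(s0, s1)
        if u < ppe:
            _deposit(sumd, sqd, tmp, last, idx, e * w, h)
            return s0, s1
        if u < ppe + pray:
            # coherent: direction change only (Thomson-like angular law)
            while True:
                u1, s0, s1 = _xs_rand(s0, s1)
                u2, s0, s1 = _xs_rand(s0, s1)
                mu_c = 2.0 * u1 - 1.0
                if u2 <= 0.5 * (1.0 + mu_c * mu_c):
                    break
            uph, s0, s1 = _xs_rand(s0, s1)
            ux, uy, uz = _rotate(ux, uy, uz, mu_c, 2.0 * math.pi * uph)
            continue
        # incoherent (Compton)
        cost, eps, s0, s1 = _kn_sample_one(e, s0, s1)
        _deposit(sumd, sqd, tmp, last, idx, e * (1.0 - eps) * w, h)
        e = e * eps
        if e <= ecut:
            _deposit(sumd, sqd, tmp, last, idx, e * w, h)
            return s0, s1
        uph, s0, s1 = _xs_rand(s0, s1)
        ux, uy, uz = _rotate(ux, uy, uz, cost, 2.0 * math.pi * uph)


@njit(cache=True)
def _scan_kernel(dens, matid, dx, dy, dz, lox, loy, loz,
                 isox, isoy, sid, n_beams, slice_z,
                 phi_max, psi_max, t_al_max, mu_al,
                 spec_cdf, spec_e, lg, mu_dens, p_pe, p_ray,
                 ecut, n_hist, s0, s1,
                 sumd, sqd, tmp, last):
    for h in range(n_hist):
        u, s0, s1 = _xs_rand(s0, s1)
        b = int(u * n_beams)
        if b >= n_beams:
            b = n_beams - 1
        theta = 2.0 * math.pi * b / n_beams
        u, s0, s1 = _xs_rand(s0, s1)
        isl = int(u * slice_z.shape[0])
        if isl >= slice_z.shape[0]:
            isl = slice_z.shape[0] - 1
        zs = slice_z[isl]
        # energy: inverse CDF over spectrum bins
        u, s0, s1 = _xs_rand(s0, s1)
        lo = 0
        hi = spec_cdf.shape[0] - 1
        if u <= spec_cdf[0]:
            ie = 0
        else:
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if spec_cdf[mid] < u:
                    lo = mid
                else:
                    hi = mid
            ie = hi
        e = spec_e[ie]
        # fan geometry
        u, s0, s1 = _xs_rand(s0, s1)
        phi = (2.0 * u - 1.0) * phi_max
        u, s0, s1 = _xs_rand(s0, s1)
        psi = (2.0 * u - 1.0) * psi_max
        # bowtie: equivalent-Al attenuation as a statistical weight
        frac = abs(phi) / phi_max
        t_al = t_al_max * frac * frac
        w = math.exp(-_interp_loge(lg, mu_al, math.log(e)) * t_al)
        ct = math.cos(theta)
        st = math.sin(theta)
        px = isox + sid * ct
        py = isoy + sid * st
        pz = zs
        # central axis toward the isocenter, rotated by phi in-plane
        cphi = math.cos(phi)
        sphi = math.sin(phi)
        ax = -ct * cphi + st * sphi
        ay = -st * cphi - ct * sphi
        cpsi = math.cos(psi)
        ux = ax * cpsi
        uy = ay * cpsi
        uz = math.sin(psi)
        s0, s1 = _track(dens, matid, dx, dy, dz, lox, loy, loz,
                        px, py, pz, ux, uy, uz, e, w, ecut,
                        lg, mu_dens, p_pe, p_ray,
                        sumd, sqd, tmp, last, h, s0, s1)
    # flush pending per-history deposits
    for idx in range(tmp.shape[0]):
        v = tmp[idx]
        if v != 0.0:
            sumd[idx] += v
            sqd[idx] += v * v
            tmp[idx] = 0.0


@njit(cache=True)
def _parallel_kernel(dens, matid, dx, dy, dz, lox, loy, loz,
                     y_half, z_half, spec_cdf, spec_e,
                     lg, mu_dens, p_pe, p_ray,
                     ecut, n_hist, s0, s1,
                     sumd, sqd, tmp, last):
    """Broad parallel beam along +x covering |y|,|z| <= half-widths."""
    for h in range(n_hist):
        u, s0, s1 = _xs_rand(s0, s1)
        py = (2.0 * u - 1.0) * y_half
        u, s0, s1 = _xs_rand(s0, s1)
        pz = (2.0 * u - 1.0) * z_half
        u, s0, s1 = _xs_rand(s0, s1)
        lo = 0
        hi = spec_cdf.shape[0] - 1
        if u <= spec_cdf[0]:
            ie = 0
        else:
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if spec_cdf[mid] < u:
                    lo = mid
                else:
                    hi = mid
            ie = hi
        e = spec_e[ie]
        s0, s1 = _track(dens, matid, dx, dy, dz, lox, loy, loz,
                        lox - 1.0, py, pz, 1.0, 0.0, 0.0, e, 1.0, ecut,
                        lg, mu_dens, p_pe, p_ray,
                        sumd, sqd, tmp, last, h, s0, s1)
    for idx in range(tmp.shape[0]):
        v = tmp[idx]
        if v != 0.0:
            sumd[idx] += v
            sqd[idx] += v * v
            tmp[idx] = 0.0


@njit(cache=True)
def _transmission_kernel(dens, matid, dx, dy, dz, lox, loy, loz,
                         px, py, pz, ux, uy, uz, loge,
                         lg, mu_dens, n_hist, s0, s1):
    """Count photons whose sampled free path exceeds the total optical
    depth along the ray (uncollided transmission)."""
    n_pass = 0
    nx, ny, nz = dens.shape
    # total optical depth once (deterministic), then Bernoulli per photon
    hx = lox + nx * dx
    hy = loy + ny * dy
    hz = loz + nz * dz
    t0 = 0.0
    t1 = 1e30
    for axx in range(3):
        if axx == 0:
            r, s, lo, hi = ux, px, lox, hx
        elif axx == 1:
            r, s, lo, hi = uy, py, loy, hy
        else:
            r, s, lo, hi = uz, pz, loz, hz
        if abs(r) < 1e-12:
            if s < lo or s > hi:
                return n_hist, s0, s1
        else:
            ta = (lo - s) / r
            tb = (hi - s) / r
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return n_hist, s0, s1
    tau_tot = 0.0
    tm = t0 + 1e-9
    i = min(max(int(math.floor((px + tm * ux - lox) / dx)), 0), nx - 1)
    j = min(max(int(math.floor((py + tm * uy - loy) / dy)), 0), ny - 1)
    k = min(max(int(math.floor((pz + tm * uz - loz) / dz)), 0), nz - 1)
    big = 1e30
    si = 1 if ux > 0 else (-1 if ux < 0 else 0)
    sj = 1 if uy > 0 else (-1 if uy < 0 else 0)
    sk = 1 if uz > 0 else (-1 if uz < 0 else 0)
    tmx = ((lox + (i + (1 if ux > 0 else 0)) * dx) - px) / ux if si != 0 else big
    tdx = dx / abs(ux) if si != 0 else big
    tmy = ((loy + (j + (1 if uy > 0 else 0)) * dy) - py) / uy if sj != 0 else big
    tdy = dy / abs(uy) if sj != 0 else big
    tmz = ((loz + (k + (1 if uz > 0 else 0)) * dz) - pz) / uz if sk != 0 else big
    tdz = dz / abs(uz) if sk != 0 else big
    t = t0
    while t < t1 - 1e-12:
        tn = tmx
        axis = 0
        if tmy < tn:
            tn = tmy
            axis = 1
        if tmz < tn:
            tn = tmz
            axis = 2
        if tn > t1:
            tn = t1
            axis = -1
        m = matid[i, j, k]
        tau_tot += _interp_loge(lg, mu_dens[m], loge) * dens[i, j, k] * (tn - t)
        t = tn
        if axis == 0:
            i += si
            tmx += tdx
            if i < 0 or i >= nx:
                break
        elif axis == 1:
            j += sj
            tmy += tdy
            if j < 0 or j >= ny:
                break
        elif axis == 2:
            k += sk
            tmz += tdz
            if k < 0 or k >= nz:
                break
        else:
            break
    for _ in range(n_hist):
        u, s0, s1 = _xs_rand(s0, s1)
        if -math.log(1.0 - u) > tau_tot:
            n_pass += 1
    return n_pass, s0, s1


# ---------------------------------------------------------------------------
# python drivers


@dataclass
class McResult:
    dose: DoseGrid  # relative, normalized to the in-body global maximum
    sigma: np.ndarray  # per-voxel relative standard deviation of the mean
    n_histories: int
    seed: int
    rng_name: str = RNG_NAME
    #: total (weighted) energy deposited in the grid, keV — bounded above by
    #: the total emitted energy, useful as a conservation check
    total_deposited_keV: float = 0.0


def _material_arrays(tables: MaterialTables):
    lg = np.log(tables.energies)
    n_mat = len(MATERIAL_NAMES)
    mu_dens = np.zeros((n_mat, lg.size))
    p_pe = np.zeros((n_mat, lg.size))
    p_ray = np.zeros((n_mat, lg.size))
    for m, name in enumerate(MATERIAL_NAMES):
        pe = tables.photoelectric[name]
        co = tables.compton[name]
        ra = tables.rayleigh[name]
        tot = pe + co + ra
        # linear attenuation per mm per unit relative electron density
        mu_dens[m] = tot * MASS_PER_EDENSITY[m] / 10.0
        p_pe[m] = pe / tot
        p_ray[m] = ra / tot
    al_tot = (tables.photoelectric["aluminum"] + tables.compton["aluminum"]
              + tables.rayleigh["aluminum"])
    mu_al = al_tot * AL_DENSITY / 10.0  # per mm of aluminium
    return lg, mu_dens, p_pe, p_ray, mu_al


def material_ids(density: VoxelGrid) -> np.ndarray:
    """Band the relative electron density into air/lung/soft-tissue/bone."""
    _require_density(density)
    d = density.values
    out = np.zeros(d.shape, dtype=np.uint8)
    out[d >= DENSITY_BANDS[0]] = 1
    out[d >= DENSITY_BANDS[1]] = 2
    out[d >= DENSITY_BANDS[2]] = 3
    return out


@dataclass
class McOptions:
    e_cutoff_keV: float = 1.0
    body_threshold: float = 0.2  # normalization mask
    min_density: float = 0.01  # below this, dose is reported as 0


def run_mc_scan(density: VoxelGrid, spec: ScanSpec, model: BeamModel,
                n_histories: int, seed: int,
                spectrum: Spectrum | None = None,
                tables: MaterialTables | None = None,
                options: McOptions | None = None) -> McResult:
    """Rotational fan-beam Monte Carlo dose on a density grid.

    The relative dose is energy deposited per unit relative electron
    density, normalized by the global maximum over body voxels
    (density > ``body_threshold``).
    """
    if n_histories <= 0:
        raise ConfigurationError("n_histories must be positive")
    _require_density(density)
    _require_commissioned(spec, model)
    options = options or McOptions()
    spectrum = spectrum or load_spectrum()
    tables = tables or load_material_tables()
    if spectrum.energies.max() > spec.kvp + 1e-9:
        raise ConfigurationError("spectrum exceeds the scan tube potential")

    lg, mu_dens, p_pe, p_ray, mu_al = _material_arrays(tables)
    matid = material_ids(density)
    dens = np.ascontiguousarray(density.values, dtype=np.float64)
    lo, _ = density.bounds()
    n_vox = int(np.prod(density.shape))
    sumd = np.zeros(n_vox)
    sqd = np.zeros(n_vox)
    tmp = np.zeros(n_vox)
    last = np.full(n_vox, -1, dtype=np.int64)
    s0, s1 = _seed_state(seed)
    phi_max = math.atan(FAN_HALF_WIDTH_MM[spec.bowtie] / spec.sid)
    psi_max = math.atan(0.5 * spec.beam_width / spec.sid)
    _scan_kernel(dens, matid,
                 density.spacing[0], density.spacing[1], density.spacing[2],
                 lo[0], lo[1], lo[2],
                 spec.isocenter[0], spec.isocenter[1], spec.sid,
                 spec.n_beams, np.asarray(spec.slice_z_positions, dtype=np.float64),
                 phi_max, psi_max, BOWTIE_AL_TMAX_MM[spec.bowtie], mu_al,
                 spectrum.cdf(), spectrum.energies, lg, mu_dens, p_pe, p_ray,
                 options.e_cutoff_keV, int(n_histories), s0, s1,
                 sumd, sqd, tmp, last)

    n = float(n_histories)
    total_dep = float(sumd.sum())
    mean = sumd / n
    var_mean = np.maximum(sqd / n - mean**2, 0.0) / max(n - 1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_sigma = np.where(mean > 0, np.sqrt(var_mean) / np.where(mean > 0, mean, 1.0), 0.0)
    mean = mean.reshape(density.shape)
    rel_sigma = rel_sigma.reshape(density.shape)
    dose = np.where(density.values >= options.min_density,
                    mean / np.maximum(density.values, options.min_density), 0.0)
    body = density.values > options.body_threshold
    mx = dose[body].max() if np.any(body) else dose.max()
    if mx <= 0:
        raise ConfigurationError("no energy deposited; increase n_histories")
    dose_grid = DoseGrid(values=dose / mx, spacing=density.spacing,
                         origin=density.origin, kind="relative",
                         sigma=rel_sigma)
    return McResult(dose=dose_grid, sigma=rel_sigma,
                    n_histories=int(n_histories), seed=int(seed),
                    total_deposited_keV=total_dep)


def uncollided_transmission(density: VoxelGrid, energy_keV: float,
                            src, direction, n_histories: int, seed: int,
                            tables: MaterialTables | None = None) -> float:
    """Fraction of photons whose sampled free path crosses the whole grid
    uncollided along one ray (Beer-Lambert check)."""
    if n_histories <= 0:
        raise ConfigurationError("n_histories must be positive")
    _require_density(density)
    tables = tables or load_material_tables()
    lg, mu_dens, _, _, _ = _material_arrays(tables)
    matid = material_ids(density)
    lo, _ = density.bounds()
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s = np.asarray(src, dtype=float)
    s0, s1 = _seed_state(seed)
    n_pass, _, _ = _transmission_kernel(
        np.ascontiguousarray(density.values, dtype=np.float64), matid,
        density.spacing[0], density.spacing[1], density.spacing[2],
        lo[0], lo[1], lo[2],
        s[0], s[1], s[2], d[0], d[1], d[2], math.log(energy_keV),
        lg, mu_dens, int(n_histories), s0, s1)
    return n_pass / float(n_histories)


def parallel_beam_depth_dose(slab_thickness: float = 300.0,
                             n_histories: int = 200_000,
                             seed: int = 0,
                             spacing: tuple[float, float, float] = (2.0, 4.0, 4.0),
                             lateral_mm: float = 150.0,
                             field_half_mm: float = 60.0,
                             central_half_mm: float = 30.0,
                             spectrum: Spectrum | None = None,
                             tables: MaterialTables | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Broad-beam depth-dose curve in a water slab, from the packaged MC
    physics: a parallel beam enters along +x and the dose averaged over the
    central field per depth layer is returned normalized to its maximum.

    This is the Monte Carlo commissioning arm: the returned curve can be
    fed to the synthetic beam-model generator as a TMR override so the
    engine and the MC share identical depth physics.
    """
    spectrum = spectrum or load_spectrum()
    tables = tables or load_material_tables()
    nx = int(round(slab_thickness / spacing[0]))
    ny = int(round(lateral_mm / spacing[1])) | 1
    nz = int(round(lateral_mm / spacing[2])) | 1
    vals = np.ones((nx, ny, nz))
    origin = (0.5 * spacing[0],
              -(ny - 1) / 2.0 * spacing[1],
              -(nz - 1) / 2.0 * spacing[2])
    water = VoxelGrid(values=vals, spacing=spacing, origin=origin,
                      value_kind="density")
    lg, mu_dens, p_pe, p_ray, _ = _material_arrays(tables)
    matid = material_ids(water)
    lo, _ = water.bounds()
    n_vox = int(np.prod(water.shape))
    sumd = np.zeros(n_vox)
    sqd = np.zeros(n_vox)
    tmp = np.zeros(n_vox)
    last = np.full(n_vox, -1, dtype=np.int64)
    s0, s1 = _seed_state(seed)
    _parallel_kernel(np.ascontiguousarray(vals), matid,
                     spacing[0], spacing[1], spacing[2],
                     lo[0], lo[1], lo[2],
                     field_half_mm, field_half_mm,
                     spectrum.cdf(), spectrum.energies,
                     lg, mu_dens, p_pe, p_ray,
                     1.0, int(n_histories), s0, s1,
                     sumd, sqd, tmp, last)
    mean = sumd.reshape(water.shape)
    y = water.axis_coords(1)
    z = water.axis_coords(2)
    ysel = np.abs(y) <= central_half_mm
    zsel = np.abs(z) <= central_half_mm
    curve = mean[:, ysel][:, :, zsel].mean(axis=(1, 2))
    depths = water.axis_coords(0)
    curve = curve / curve.max()
    # prepend the surface node required by the TMR contract (depth 0) and
    # flatten any small scatter buildup so the curve is non-increasing with
    # its maximum at the surface node
    depths = np.concatenate(([0.0], depths))
    curve = np.concatenate(([curve[0]], curve))
    curve = np.minimum.accumulate(curve)
    curve = curve / curve[0]
    return depths, curve
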