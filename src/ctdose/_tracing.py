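"""Numba kernels shared by the dose engine: interpolation, Siddon-style
incremental voxel traversal, and the per-beam dose loop.

All kernels work in the scanner-fixed frame: grids are indexed [ix, iy, iz],
voxel (0,0,0) is centered at ``origin`` and the grid box extends half a voxel
beyond the outermost voxel centers.
"""

import math

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def interp1(xs, ys, x):
    """Piecewise-linear interpolation with endpoint clamping (scalar)."""
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    w = (x - xs[lo]) / (xs[lo + 1] - xs[lo])
    return ys[lo] + w * (ys[lo + 1] - ys[lo])


@njit(cache=True)
def tmr_eval(depths, values, tail_mu, d):
    """TMR lookup: linear inside the table, exponential tail beyond it."""
    last = depths.shape[0] - 1
    if d <= depths[last]:
        return interp1(depths, values, d)
    return values[last] * math.exp(-tail_mu * (d - depths[last]))


@njit(cache=True)
def ray_depth(dens, dx, dy, dz, lox, loy, loz, sx, sy, sz, px, py, pz):
    """Radiological depth: line integral of ``dens`` from the grid entry of
    the ray src->pt up to pt, by exact incremental boundary crossing.

    ``(lox, loy, loz)`` is the low corner of the grid box (origin minus half
    a voxel).  Returns 0 if the ray misses the box entirely.
    """
    nx, ny, nz = dens.shape
    hix = lox + nx * dx
    hiy = loy + ny * dy
    hiz = loz + nz * dz
    rx = px - sx
    ry = py - sy
    rz = pz - sz
    length = math.sqrt(rx * rx + ry * ry + rz * rz)
    if length <= 0.0:
        return 0.0

    # clip parameter t in [0, 1] to the box
    t0 = 0.0
    t1 = 1.0
    for ax in range(3):
        if ax == 0:
            r, s, lo, hi = rx, sx, lox, hix
        elif ax == 1:
            r, s, lo, hi = ry, sy, loy, hiy
        else:
            r, s, lo, hi = rz, sz, loz, hiz
        if abs(r) < _EPS:
            if s < lo or s > hi:
                return 0.0
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
        return 0.0

    # starting voxel just inside the entry point
    tmid = t0 + 1e-9 * (t1 - t0)
    x0 = sx + tmid * rx
    y0 = sy + tmid * ry
    z0 = sz + tmid * rz
    i = int(math.floor((x0 - lox) / dx))
    j = int(math.floor((y0 - loy) / dy))
    k = int(math.floor((z0 - loz) / dz))
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
    if abs(rx) > _EPS:
        step_i = 1 if rx > 0 else -1
        nxt = lox + (i + (1 if rx > 0 else 0)) * dx
        tmax_x = (nxt - sx) / rx
        tdel_x = dx / abs(rx)
    else:
        step_i = 0
        tmax_x = big
        tdel_x = big
    if abs(ry) > _EPS:
        step_j = 1 if ry > 0 else -1
        nxt = loy + (j + (1 if ry > 0 else 0)) * dy
        tmax_y = (nxt - sy) / ry
        tdel_y = dy / abs(ry)
    else:
        step_j = 0
        tmax_y = big
        tdel_y = big
    if abs(rz) > _EPS:
        step_k = 1 if rz > 0 else -1
        nxt = loz + (k + (1 if rz > 0 else 0)) * dz
        tmax_z = (nxt - sz) / rz
        tdel_z = dz / abs(rz)
    else:
        step_k = 0
        tmax_z = big
        tdel_z = big

    acc = 0.0
    t = t0
    while t < t1 - _EPS:
        tn = tmax_x
        axis = 0
        if tmax_y < tn:
            tn = tmax_y
            axis = 1
        if tmax_z < tn:
            tn = tmax_z
            axis = 2
        if tn > t1:
            tn = t1
            axis = -1
        acc += dens[i, j, k] * (tn - t) * length
        t = tn
        if axis == 0:
            i += step_i
            tmax_x += tdel_x
            if i < 0 or i >= nx:
                break
        elif axis == 1:
            j += step_j
            tmax_y += tdel_y
            if j < 0 or j >= ny:
                break
        elif axis == 2:
            k += step_k
            tmax_z += tdel_z
            if k < 0 or k >= nz:
                break
        else:
            break
    return acc


@njit(cache=True)
def beam_kernel(dens, dx, dy, dz, ox, oy, oz,
                sx, sy, sz, ux, uy, sid,
                tmr_d, tmr_v, tail_mu,
                px_off, px_val, pz_off, pz_val,
                use_invsq, cutoff, out):
    """Single-beam semi-empirical dose:

    D(p) = TMR(d_eff) * Px(x_off) * Pz(z_off) * (sid / r)^2

    with x_off/z_off the voxel offsets projected along the ray onto the
    isocenter plane and d_eff the radiological depth from the phantom
    surface.  Voxels whose projected profile product falls below ``cutoff``
    are left at zero (truncated profile tails).  Adds into ``out``.
    """
    nx, ny, nz = dens.shape
    lox = ox - 0.5 * dx
    loy = oy - 0.5 * dy
    loz = oz - 0.5 * dz
    # in-plane unit vector perpendicular to the central axis
    ex0 = -uy
    ex1 = ux
    sid2 = sid * sid
    for i in range(nx):
        x = ox + i * dx
        for j in range(ny):
            y = oy + j * dy
            vx = x - sx
            vy = y - sy
            t = vx * ux + vy * uy
            if t < 1e-6:
                continue  # behind the source
            scale = sid / t
            xoff = (vx * ex0 + vy * ex1) * scale
            px = interp1(px_off, px_val, xoff)
            if px < cutoff:
                continue
            for k in range(nz):
                z = oz + k * dz
                vz = z - sz
                zoff = vz * scale
                pz = interp1(pz_off, pz_val, zoff)
                f = px * pz
                if f < cutoff:
                    continue
                d = ray_depth(dens, dx, dy, dz, lox, loy, loz,
                              sx, sy, sz, x, y, z)
                f *= tmr_eval(tmr_d, tmr_v, tail_mu, d)
                if use_invsq:
                    r2 = vx * vx + vy * vy + vz * vz
                    f *= sid2 / r2
                out[i, j, k] += f
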