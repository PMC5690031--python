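"""Compiled transport kernels.

Everything here is numba-compiled and operates on plain arrays prepared by
``kvdose.transport``: a uint8 material-index grid, per-material linear
attenuation / interaction-split / kerma tables on the 1 keV energy grid,
and discretized source sampling tables.

Ray tracing is exact voxel traversal (Amanatides-Woo).  The biased engine
forces the first interaction inside the grid (weight 1 - exp(-tau_exit)),
applies survival biasing at each collision (weight times the scatter
probability, so photoabsorption never kills a history outright), scores
every collision at all points of interest by next-event estimation, and
continues with analog free flights plus Russian roulette.  Incoherent
scattering samples the Klein-Nishina law by Kahn's rejection method;
coherent scattering is Thomson-shaped with the photon energy unchanged.

A plain analog Monte Carlo with a track-length fluence tally in a sphere
is included as an independent reference estimator for cross-checks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEC2 = 510.998950  # keV
E_MIN = 5.0        # keV, grid start and transport cutoff
WEIGHT_CUTOFF = 1e-3
ROULETTE_SURVIVAL = 0.1  # survival probability; survivors gain 10x weight
MAX_GENERATIONS = 10000


@njit(cache=True)
def _mu_at(table, energy):
    """Linear interpolation of per-material rows at a continuous energy."""
    n_mat, n_e = table.shape
    x = energy - E_MIN
    i0 = int(x)
    if i0 < 0:
        i0 = 0
    if i0 > n_e - 2:
        i0 = n_e - 2
    f = x - i0
    if f < 0.0:
        f = 0.0
    if f > 1.0:
        f = 1.0
    out = np.empty(n_mat)
    for m in range(n_mat):
        out[m] = table[m, i0] * (1.0 - f) + table[m, i0 + 1] * f
    return out


@njit(cache=True)
def _interp_row(row, energy):
    n_e = row.shape[0]
    x = energy - E_MIN
    i0 = int(x)
    if i0 < 0:
        i0 = 0
    if i0 > n_e - 2:
        i0 = n_e - 2
    f = x - i0
    if f < 0.0:
        f = 0.0
    if f > 1.0:
        f = 1.0
    return row[i0] * (1.0 - f) + row[i0 + 1] * f


@njit(cache=True)
def _ray_box(px, py, pz, dx, dy, dz, lo, hi):
    """Slab intersection of an infinite ray with the grid box -> (t0, t1)."""
    t0 = -1e30
    t1 = 1e30
    p = (px, py, pz)
    d = (dx, dy, dz)
    for a in range(3):
        if abs(d[a]) < 1e-14:
            if p[a] <= lo[a] or p[a] >= hi[a]:
                return 1.0, -1.0  # miss
        else:
            ta = (lo[a] - p[a]) / d[a]
            tb = (hi[a] - p[a]) / d[a]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True)
def _dda_tau(px, py, pz, dx, dy, dz, t_start, t_end, mats, lo, sp, mu_e):
    """Optical depth accumulated along t in [t_start, t_end] of a unit ray."""
    nx, ny, nz = mats.shape
    eps = 1e-9
    t = t_start
    tau = 0.0
    # entry voxel
    ix = int((px + (t + eps) * dx - lo[0]) / sp[0])
    iy = int((py + (t + eps) * dy - lo[1]) / sp[1])
    iz = int((pz + (t + eps) * dz - lo[2]) / sp[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    sz = 1 if dz > 0 else -1
    big = 1e30
    if dx != 0.0:
        tx = ((lo[0] + (ix + (1 if sx > 0 else 0)) * sp[0]) - px) / dx
        dtx = sp[0] / abs(dx)
    else:
        tx = big
        dtx = big
    if dy != 0.0:
        ty = ((lo[1] + (iy + (1 if sy > 0 else 0)) * sp[1]) - py) / dy
        dty = sp[1] / abs(dy)
    else:
        ty = big
        dty = big
    if dz != 0.0:
        tz = ((lo[2] + (iz + (1 if sz > 0 else 0)) * sp[2]) - pz) / dz
        dtz = sp[2] / abs(dz)
    else:
        tz = big
        dtz = big
    while t < t_end - 1e-12:
        # next boundary
        tn = tx
        axis = 0
        if ty < tn:
            tn = ty
            axis = 1
        if tz < tn:
            tn = tz
            axis = 2
        seg_end = tn if tn < t_end else t_end
        if seg_end > t:
            tau += mu_e[mats[ix, iy, iz]] * (seg_end - t)
            t = seg_end
        if tn >= t_end:
            break
        if axis == 0:
            ix += sx
            tx += dtx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += sy
            ty += dty
            if iy < 0 or iy >= ny:
                break
        else:
            iz += sz
            tz += dtz
            if iz < 0 or iz >= nz:
                break
    return tau


@njit(cache=True)
def _dda_locate(px, py, pz, dx, dy, dz, t_start, t_end, tau_target,
                mats, lo, sp, mu_e):
    """Walk until cumulative optical depth reaches tau_target.

    Returns (hit, t_hit, mat).  hit = 0 if the ray leaves [t_start, t_end]
    before accumulating tau_target.
    """
    nx, ny, nz = mats.shape
    eps = 1e-9
    t = t_start
    tau = 0.0
    ix = int((px + (t + eps) * dx - lo[0]) / sp[0])
    iy = int((py + (t + eps) * dy - lo[1]) / sp[1])
    iz = int((pz + (t + eps) * dz - lo[2]) / sp[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    sz = 1 if dz > 0 else -1
    big = 1e30
    if dx != 0.0:
        tx = ((lo[0] + (ix + (1 if sx > 0 else 0)) * sp[0]) - px) / dx
        dtx = sp[0] / abs(dx)
    else:
        tx = big
        dtx = big
    if dy != 0.0:
        ty = ((lo[1] + (iy + (1 if sy > 0 else 0)) * sp[1]) - py) / dy
        dty = sp[1] / abs(dy)
    else:
        ty = big
        dty = big
    if dz != 0.0:
        tz = ((lo[2] + (iz + (1 if sz > 0 else 0)) * sp[2]) - pz) / dz
        dtz = sp[2] / abs(dz)
    else:
        tz = big
        dtz = big
    while t < t_end - 1e-12:
        tn = tx
        axis = 0
        if ty < tn:
            tn = ty
            axis = 1
        if tz < tn:
            tn = tz
            axis = 2
        seg_end = tn if tn < t_end else t_end
        mu = mu_e[mats[ix, iy, iz]]
        if seg_end > t:
            dtau = mu * (seg_end - t)
            if tau + dtau >= tau_target and mu > 0.0:
                t_hit = t + (tau_target - tau) / mu
                return 1, t_hit, mats[ix, iy, iz]
            tau += dtau
            t = seg_end
        if tn >= t_end:
            break
        if axis == 0:
            ix += sx
            tx += dtx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += sy
            ty += dty
            if iy < 0 or iy >= ny:
                break
        else:
            iz += sz
            tz += dtz
            if iz < 0 or iz >= nz:
                break
    return 0, t_end, np.uint8(0)


@njit(cache=True)
def _segment_tau(ax, ay, az, bx, by, bz, mats, lo, sp, mu_e):
    """Optical depth between two points (clipped to the grid box)."""
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < 1e-12:
        return 0.0
    dx /= length
    dy /= length
    dz /= length
    hi = (lo[0] + mats.shape[0] * sp[0], lo[1] + mats.shape[1] * sp[1],
          lo[2] + mats.shape[2] * sp[2])
    t0, t1 = _ray_box(ax, ay, az, dx, dy, dz, lo, hi)
    if t1 <= t0:
        return 0.0
    ts = t0 if t0 > 0.0 else 0.0
    te = t1 if t1 < length else length
    if te <= ts:
        return 0.0
    return _dda_tau(ax, ay, az, dx, dy, dz, ts, te, mats, lo, sp, mu_e)


@njit(cache=True)
def _mat_lengths(ax, ay, az, bx, by, bz, mats, lo, sp, out):
    """Per-material chord lengths between two points (cm)."""
    for m in range(out.shape[0]):
        out[m] = 0.0
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < 1e-12:
        return
    dx /= length
    dy /= length
    dz /= length
    nx, ny, nz = mats.shape
    hi = (lo[0] + nx * sp[0], lo[1] + ny * sp[1], lo[2] + nz * sp[2])
    t0, t1 = _ray_box(ax, ay, az, dx, dy, dz, lo, hi)
    if t1 <= t0:
        return
    t = t0 if t0 > 0.0 else 0.0
    t_end = t1 if t1 < length else length
    if t_end <= t:
        return
    eps = 1e-9
    ix = int((ax + (t + eps) * dx - lo[0]) / sp[0])
    iy = int((ay + (t + eps) * dy - lo[1]) / sp[1])
    iz = int((az + (t + eps) * dz - lo[2]) / sp[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    sz = 1 if dz > 0 else -1
    big = 1e30
    if dx != 0.0:
        tx = ((lo[0] + (ix + (1 if sx > 0 else 0)) * sp[0]) - ax) / dx
        dtx = sp[0] / abs(dx)
    else:
        tx = big
        dtx = big
    if dy != 0.0:
        ty = ((lo[1] + (iy + (1 if sy > 0 else 0)) * sp[1]) - ay) / dy
        dty = sp[1] / abs(dy)
    else:
        ty = big
        dty = big
    if dz != 0.0:
        tz = ((lo[2] + (iz + (1 if sz > 0 else 0)) * sp[2]) - az) / dz
        dtz = sp[2] / abs(dz)
    else:
        tz = big
        dtz = big
    while t < t_end - 1e-12:
        tn = tx
        axis = 0
        if ty < tn:
            tn = ty
            axis = 1
        if tz < tn:
            tn = tz
            axis = 2
        seg_end = tn if tn < t_end else t_end
        if seg_end > t:
            out[mats[ix, iy, iz]] += seg_end - t
            t = seg_end
        if tn >= t_end:
            break
        if axis == 0:
            ix += sx
            tx += dtx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += sy
            ty += dty
            if iy < 0 or iy >= ny:
                break
        else:
            iz += sz
            tz += dtz
            if iz < 0 or iz >= nz:
                break


@njit(cache=True)
def _kn_sigma_re2(k):
    """Klein-Nishina total cross section per electron in units of r_e^2."""
    t = 1.0 + 2.0 * k
    s = (1.0 + k) / (k * k) * (2.0 * (1.0 + k) / t - np.log(t) / k)
    s += np.log(t) / (2.0 * k) - (1.0 + 3.0 * k) / (t * t)
    return 2.0 * np.pi * s


@njit(cache=True)
def _kn_pdf(k, cost, sigma_re2):
    """Normalized Klein-Nishina angular pdf (per steradian)."""
    r = 1.0 / (1.0 + k * (1.0 - cost))
    return 0.5 * r * r * (r + 1.0 / r - (1.0 - cost * cost)) / sigma_re2


@njit(cache=True)
def _sample_kn(k):
    """Kahn's rejection sampling of the Klein-Nishina law -> cos(theta)."""
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k):
            x = 1.0 + 2.0 * k * r2  # x = E/E'
            if r3 <= 4.0 * (x - 1.0) / (x * x):
                return 1.0 - (x - 1.0) / k
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            cost = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (cost * cost + 1.0 / x):
                return cost


@njit(cache=True)
def _sample_thomson():
    """cos(theta) from the Thomson shape (1 + cos^2)."""
    while True:
        cost = 2.0 * np.random.random() - 1.0
        if 2.0 * np.random.random() <= 1.0 + cost * cost:
            return cost


@njit(cache=True)
def _rotate(dx, dy, dz, cost, phi):
    """Rotate a unit vector by polar angle (cost) and azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(dz) < 0.99999:
        # u = d x z_hat etc.: build orthonormal frame
        den = np.sqrt(dx * dx + dy * dy)
        ux = dy / den
        uy = -dx / den
        uz = 0.0
        vx = uy * dz - uz * dy
        vy = uz * dx - ux * dz
        vz = ux * dy - uy * dx
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
        vx = uy * dz - uz * dy
        vy = uz * dx - ux * dz
        vz = ux * dy - uy * dx
    nx = cost * dx + sint * (cosp * ux + sinp * vx)
    ny = cost * dy + sint * (cosp * uy + sinp * vy)
    nz = cost * dz + sint * (cosp * uz + sinp * vz)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _sample_cdf(edges, cdf, xi):
    n = edges.shape[0] - 1
    i = np.searchsorted(cdf, xi) - 1
    if i < 0:
        i = 0
    if i > n - 1:
        i = n - 1
    span = cdf[i + 1] - cdf[i]
    f = (xi - cdf[i]) / span if span > 0 else 0.5
    return i, edges[i] + f * (edges[i + 1] - edges[i])


@njit(cache=True)
def _history_seed(seed, h):
    """Splitmix-style hash of (seed, history) -> 31-bit per-history seed.

    Seeding every history independently keeps runs with slightly perturbed
    geometry (e.g., one substituted voxel) correlated history-by-history,
    which is what makes same-seed dose ratios nearly noise-free.
    """
    z = np.uint64(seed) + np.uint64(h + 1) * np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return np.int64(z & np.uint64(0x7FFFFFFF))


@njit(cache=True)
def _sample_source(sad, arc_start, arc_deg, u_edges, u_cdf, v_edges, v_cdf,
                   spec_cdf, e0):
    """One source photon: position, direction, energy, plane-crossing cosine."""
    gantry = arc_start + arc_deg * np.random.random()
    th = gantry * np.pi / 180.0
    sx = sad * np.sin(th)
    sy = -sad * np.cos(th)
    sz = 0.0
    iu, u = _sample_cdf(u_edges, u_cdf, np.random.random())
    iv, v = _sample_cdf(v_edges, v_cdf, np.random.random())
    row = spec_cdf[iu]
    xi = np.random.random()
    ie = np.searchsorted(row, xi)
    if ie > row.shape[0] - 1:
        ie = row.shape[0] - 1
    energy = E_MIN + e0 + ie
    # target point on the isocenter plane
    tx = u * np.cos(th)
    ty = u * np.sin(th)
    tz = v
    dx = tx - sx
    dy = ty - sy
    dz = tz - sz
    norm = np.sqrt(dx * dx + dy * dy + dz * dz)
    dx /= norm
    dy /= norm
    dz /= norm
    cos_psi = sad / norm  # ray vs plane-normal cosine
    return sx, sy, sz, dx, dy, dz, float(energy), cos_psi


@njit(cache=True)
def scatter_kernel(seed, n, n_batch, mats, lo, sp, mu_tot, p_scat, p_coh,
                   kerma_poi, pois, d_min2, sad, arc_start, arc_deg,
                   u_edges, u_cdf, v_edges, v_cdf, spec_cdf, e0,
                   rec_cap):
    """Biased scatter transport with next-event estimation at the POIs.

    Returns per-batch first- and multiple-scatter tallies (sums of per-
    history contributions; caller normalizes), plus the recorded scatter
    population when rec_cap > 0.
    """
    n_poi = pois.shape[0]
    first = np.zeros((n_batch, n_poi))
    mult = np.zeros((n_batch, n_poi))
    rec_n = 0
    rec_pos = np.empty((rec_cap, 3))
    rec_dir = np.empty((rec_cap, 3))
    rec_e = np.empty(rec_cap)
    rec_w = np.empty(rec_cap)
    rec_gen = np.empty(rec_cap, dtype=np.int64)
    rec_hist = np.empty(rec_cap, dtype=np.int64)
    hi = (lo[0] + mats.shape[0] * sp[0], lo[1] + mats.shape[1] * sp[1],
          lo[2] + mats.shape[2] * sp[2])

    for h in range(n):
        np.random.seed(_history_seed(seed, h))
        b = h * n_batch // n
        sx, sy, sz, dx, dy, dz, energy, cos_psi = _sample_source(
            sad, arc_start, arc_deg, u_edges, u_cdf, v_edges, v_cdf,
            spec_cdf, e0)
        mu_e = _mu_at(mu_tot, energy)
        t0, t1 = _ray_box(sx, sy, sz, dx, dy, dz, lo, hi)
        if t1 <= t0:
            continue
        ts = t0 if t0 > 0.0 else 0.0
        tau_exit = _dda_tau(sx, sy, sz, dx, dy, dz, ts, t1, mats, lo, sp, mu_e)
        if tau_exit <= 1e-12:
            continue
        w = cos_psi * (1.0 - np.exp(-tau_exit))
        tau_s = -np.log(1.0 - np.random.random() * (1.0 - np.exp(-tau_exit)))
        hit, t_hit, mat = _dda_locate(sx, sy, sz, dx, dy, dz, ts, t1, tau_s,
                                      mats, lo, sp, mu_e)
        if hit == 0:
            continue
        px = sx + t_hit * dx
        py = sy + t_hit * dy
        pz = sz + t_hit * dz
        gen = 1
        while gen < MAX_GENERATIONS:
            # survival biasing: absorb the photoelectric branch into weight
            ps = _interp_row(p_scat[mat], energy)
            w *= ps
            if w <= 0.0:
                break
            coh = np.random.random() < _interp_row(p_coh[mat], energy)
            k = energy / MEC2
            sig = _kn_sigma_re2(k)
            # next-event estimation toward every POI
            for p in range(n_poi):
                qx = pois[p, 0] - px
                qy = pois[p, 1] - py
                qz = pois[p, 2] - pz
                d2 = qx * qx + qy * qy + qz * qz
                d = np.sqrt(d2)
                if d < 1e-9:
                    cost = 1.0
                else:
                    cost = (dx * qx + dy * qy + dz * qz) / d
                if coh:
                    e_out = energy
                    pdf = 3.0 / (16.0 * np.pi) * (1.0 + cost * cost)
                else:
                    r = 1.0 / (1.0 + k * (1.0 - cost))
                    e_out = energy * r
                    if e_out < E_MIN:
                        continue
                    pdf = _kn_pdf(k, cost, sig)
                mu_out = _mu_at(mu_tot, e_out)
                tau_p = _segment_tau(px, py, pz, pois[p, 0], pois[p, 1],
                                     pois[p, 2], mats, lo, sp, mu_out)
                # near-field regularization: inside the exclusion ball the
                # 1/d^2 kernel is replaced by its ball average 3/d_min^2,
                # which keeps the estimator unbiased for a locally uniform
                # collision density
                geom = 1.0 / d2 if d2 > d_min2 else 3.0 / d_min2
                contrib = w * pdf * np.exp(-tau_p) * geom * _interp_row(
                    kerma_poi[p], e_out)
                if gen == 1:
                    first[b, p] += contrib
                else:
                    mult[b, p] += contrib
            if rec_cap > 0 and rec_n < rec_cap:
                rec_pos[rec_n, 0] = px
                rec_pos[rec_n, 1] = py
                rec_pos[rec_n, 2] = pz
                rec_dir[rec_n, 0] = dx
                rec_dir[rec_n, 1] = dy
                rec_dir[rec_n, 2] = dz
                rec_e[rec_n] = energy
                rec_w[rec_n] = w
                rec_gen[rec_n] = gen
                rec_hist[rec_n] = h
                rec_n += 1
            # sample the actual outgoing photon
            if coh:
                cost = _sample_thomson()
            else:
                cost = _sample_kn(k)
                energy = energy / (1.0 + k * (1.0 - cost))
                if energy < E_MIN:
                    break
            dx, dy, dz = _rotate(dx, dy, dz, cost, 2.0 * np.pi * np.random.random())
            # analog free flight to the next collision
            mu_e = _mu_at(mu_tot, energy)
            tau_t = -np.log(np.random.random())
            t0, t1 = _ray_box(px, py, pz, dx, dy, dz, lo, hi)
            ts = 0.0
            if t1 <= ts:
                break
            hit, t_hit, mat = _dda_locate(px, py, pz, dx, dy, dz, ts, t1,
                                          tau_t, mats, lo, sp, mu_e)
            if hit == 0:
                break
            px += t_hit * dx
            py += t_hit * dy
            pz += t_hit * dz
            gen += 1
            if w < WEIGHT_CUTOFF:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    break
    return (first, mult, rec_n, rec_pos[:rec_n], rec_dir[:rec_n],
            rec_e[:rec_n], rec_w[:rec_n], rec_gen[:rec_n], rec_hist[:rec_n])


@njit(cache=True)
def nee_from_population(pos, dirs, energies, weights, gens, hists, n_hist,
                        n_batch, mats, lo, sp, mu_tot, p_coh, kerma_poi,
                        pois, d_min2):
    """Next-event estimation from a stored scatter population.

    The stored weights already include the scatter-survival factor; the
    coherent/incoherent branch is resolved by expectation (both branches
    scored with their probabilities) rather than by sampling.
    """
    n_poi = pois.shape[0]
    first = np.zeros((n_batch, n_poi))
    mult = np.zeros((n_batch, n_poi))
    for i in range(pos.shape[0]):
        b = hists[i] * n_batch // n_hist
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        energy = energies[i]
        w = weights[i]
        k = energy / MEC2
        sig = _kn_sigma_re2(k)
        # expected coherent fraction at this site
        mu_e = _mu_at(mu_tot, energy)
        # material at the site
        ix = int((px - lo[0]) / sp[0])
        iy = int((py - lo[1]) / sp[1])
        iz = int((pz - lo[2]) / sp[2])
        if ix < 0 or iy < 0 or iz < 0 or ix >= mats.shape[0] \
                or iy >= mats.shape[1] or iz >= mats.shape[2]:
            continue
        pc = _interp_row(p_coh[mats[ix, iy, iz]], energy)
        for p in range(n_poi):
            qx = pois[p, 0] - px
            qy = pois[p, 1] - py
            qz = pois[p, 2] - pz
            d2 = qx * qx + qy * qy + qz * qz
            d = np.sqrt(d2)
            cost = 1.0 if d < 1e-9 else (dx * qx + dy * qy + dz * qz) / d
            geom = 1.0 / d2 if d2 > d_min2 else 3.0 / d_min2
            contrib = 0.0
            # coherent branch
            mu_out = _mu_at(mu_tot, energy)
            tau_p = _segment_tau(px, py, pz, pois[p, 0], pois[p, 1],
                                 pois[p, 2], mats, lo, sp, mu_out)
            contrib += pc * 3.0 / (16.0 * np.pi) * (1.0 + cost * cost) \
                * np.exp(-tau_p) * _interp_row(kerma_poi[p], energy)
            # incoherent branch
            r = 1.0 / (1.0 + k * (1.0 - cost))
            e_out = energy * r
            if e_out >= E_MIN:
                mu_out2 = _mu_at(mu_tot, e_out)
                tau_q = _segment_tau(px, py, pz, pois[p, 0], pois[p, 1],
                                     pois[p, 2], mats, lo, sp, mu_out2)
                contrib += (1.0 - pc) * _kn_pdf(k, cost, sig) \
                    * np.exp(-tau_q) * _interp_row(kerma_poi[p], e_out)
            contrib *= w * geom
            if gens[i] == 1:
                first[b, p] += contrib
            else:
                mult[b, p] += contrib
    return first, mult


@njit(cache=True)
def analog_kernel(seed, n, n_batch, mats, lo, sp, mu_tot, p_abs, p_coh,
                  kerma_sphere, center, radius, sad, arc_start, arc_deg,
                  u_edges, u_cdf, v_edges, v_cdf, spec_cdf, e0):
    """Plain analog MC with a track-length fluence tally in a sphere.

    No forced interactions, no survival biasing, no next-event estimation:
    photons fly analog distances, are absorbed outright on photoelectric
    events, and every flight segment crossing the tally sphere scores
    track-length x kerma / volume.  Returns per-batch dose sums.
    """
    tally = np.zeros(n_batch)
    hi = (lo[0] + mats.shape[0] * sp[0], lo[1] + mats.shape[1] * sp[1],
          lo[2] + mats.shape[2] * sp[2])
    vol = 4.0 / 3.0 * np.pi * radius**3
    r2 = radius * radius
    for h in range(n):
        np.random.seed(_history_seed(seed, h))
        b = h * n_batch // n
        px, py, pz, dx, dy, dz, energy, cos_psi = _sample_source(
            sad, arc_start, arc_deg, u_edges, u_cdf, v_edges, v_cdf,
            spec_cdf, e0)
        w = cos_psi
        alive = True
        while alive:
            mu_e = _mu_at(mu_tot, energy)
            t0, t1 = _ray_box(px, py, pz, dx, dy, dz, lo, hi)
            if t1 <= max(t0, 0.0):
                break
            ts = t0 if t0 > 0.0 else 0.0
            tau_t = -np.log(np.random.random())
            hit, t_hit, mat = _dda_locate(px, py, pz, dx, dy, dz, ts, t1,
                                          tau_t, mats, lo, sp, mu_e)
            t_seg = t_hit if hit == 1 else t1
            # track-length tally: overlap of [0, t_seg] with the sphere
            cx = center[0] - px
            cy = center[1] - py
            cz = center[2] - pz
            tc = cx * dx + cy * dy + cz * dz
            c2 = cx * cx + cy * cy + cz * cz
            disc = tc * tc - (c2 - r2)
            if disc > 0.0:
                sq = np.sqrt(disc)
                ta = tc - sq
                tb = tc + sq
                if ta < 0.0:
                    ta = 0.0
                if tb > t_seg:
                    tb = t_seg
                if tb > ta:
                    tally[b] += w * (tb - ta) / vol * _interp_row(
                        kerma_sphere, energy)
            if hit == 0:
                break
            px += t_hit * dx
            py += t_hit * dy
            pz += t_hit * dz
            # interaction type: photoelectric absorbs, otherwise scatter
            xi = np.random.random()
            if xi < _interp_row(p_abs[mat], energy):
                break
            pc = _interp_row(p_coh[mat], energy)
            if np.random.random() < pc:
                cost = _sample_thomson()
            else:
                k = energy / MEC2
                cost = _sample_kn(k)
                energy = energy / (1.0 + k * (1.0 - cost))
                if energy < E_MIN:
                    break
            dx, dy, dz = _rotate(dx, dy, dz, cost,
                                 2.0 * np.pi * np.random.random())
    return tally
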