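"""Numba transport kernels for the voxel Monte Carlo dose engine.

Physics model (see docs/methods.md):

* electrons travel on straight continuous-slowing-down tracks with uniform
  energy deposition per unit mass path; tracks are terminated (local
  deposit) once the residual range falls below the range cut;
* photons are ray-traced voxel by voxel with per-voxel linear attenuation
  (mass coefficient of the voxel material times its density); interactions
  are photoelectric (local deposit), incoherent scatter (Klein-Nishina
  energy/angle, recoil energy deposited at the interaction point) and
  coherent scatter (direction change only); photons below the cutoff
  deposit locally, photons leaving the grid are booked as escaped.

All energies are in keV, lengths in mm, densities in g/cm^3.  The factor
0.1 converts rho * length(mm) into mass thickness in g/cm^2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-9


@njit(cache=True, inline="always")
def _loglin(loge_grid, values, loge):
    """Piecewise-linear interpolation of values on a log-energy grid."""
    n = loge_grid.shape[0]
    if loge <= loge_grid[0]:
        return values[0]
    if loge >= loge_grid[n - 1]:
        return values[n - 1]
    lo = np.searchsorted(loge_grid, loge) - 1
    f = (loge - loge_grid[lo]) / (loge_grid[lo + 1] - loge_grid[lo])
    return values[lo] + f * (values[lo + 1] - values[lo])


@njit(cache=True, inline="always")
def _isotropic():
    z = 2.0 * np.random.random() - 1.0
    phi = 2.0 * np.pi * np.random.random()
    s = np.sqrt(max(0.0, 1.0 - z * z))
    return s * np.cos(phi), s * np.sin(phi), z


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cos_t, phi):
    """Rotate unit vector d by polar angle theta and azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # orthonormal basis around d
    if abs(dz) < 0.99:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 0.0, -dz, dy
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp, sp = np.cos(phi), np.sin(phi)
    nx = cos_t * dx + sin_t * (cp * ux + sp * vx)
    ny = cos_t * dy + sin_t * (cp * uy + sp * vy)
    nz = cos_t * dz + sin_t * (cp * uz + sp * vz)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _boundary_distance(x, y, z, dx, dy, dz, h):
    """Distance to the next voxel face along direction d (positions in mm)."""
    t = 1e30
    if dx > _EPS:
        tt = ((np.floor(x / h) + 1.0) * h - x) / dx
        if tt < t:
            t = tt
    elif dx < -_EPS:
        tt = (np.floor(x / h) * h - x) / dx
        if tt < t:
            t = tt
    if dy > _EPS:
        tt = ((np.floor(y / h) + 1.0) * h - y) / dy
        if tt < t:
            t = tt
    elif dy < -_EPS:
        tt = (np.floor(y / h) * h - y) / dy
        if tt < t:
            t = tt
    if dz > _EPS:
        tt = ((np.floor(z / h) + 1.0) * h - z) / dz
        if tt < t:
            t = tt
    elif dz < -_EPS:
        tt = (np.floor(z / h) * h - z) / dz
        if tt < t:
            t = tt
    return t + 1e-4 * h  # small push across the face


@njit(cache=True, inline="always")
def _voxel_index(x, y, z, h, nx, ny, nz):
    ix = int(np.floor(x / h))
    iy = int(np.floor(y / h))
    iz = int(np.floor(z / h))
    if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
        return -1
    return (ix * ny + iy) * nz + iz


@njit(cache=True)
def _deposit_electron(
    x, y, z, dx, dy, dz, e_kev,
    density, nx, ny, nz, h,
    er_loge, er_logr, range_cut_mm,
    dose, events,
):
    """Transport one electron; returns (deposited, escaped) keV."""
    loge = np.log(e_kev)
    if e_kev <= 10.0:
        # residual range below ~0.003 g/cm^2 (< range cut in tissue)
        idx = _voxel_index(x, y, z, h, nx, ny, nz)
        if idx < 0:
            return 0.0, e_kev
        dose[idx] += e_kev
        events[idx] += 1
        return e_kev, 0.0
    r0 = np.exp(_loglin(er_loge, er_logr, loge))  # g/cm^2
    r_rem = r0
    e_rem = e_kev
    dep_per_mass = e_kev / r0
    while True:
        idx = _voxel_index(x, y, z, h, nx, ny, nz)
        if idx < 0:
            return e_kev - e_rem, e_rem
        rho = density[idx]
        if rho <= 1e-6:
            rho = 1e-6
        if r_rem / (0.1 * rho) < range_cut_mm:
            dose[idx] += e_rem
            events[idx] += 1
            return e_kev, 0.0
        t = _boundary_distance(x, y, z, dx, dy, dz, h)
        seg_mass = t * 0.1 * rho
        if seg_mass >= r_rem:
            dose[idx] += e_rem
            events[idx] += 1
            return e_kev, 0.0
        dep = dep_per_mass * seg_mass
        dose[idx] += dep
        events[idx] += 1
        e_rem -= dep
        r_rem -= seg_mass
        x += t * dx
        y += t * dy
        z += t * dz


@njit(cache=True, inline="always")
def _sample_compton(k):
    """Klein-Nishina sampling; returns (epsilon = E'/E, cos_theta)."""
    eps_min = 1.0 / (1.0 + 2.0 * k)
    bound = eps_min + 1.0 / eps_min
    while True:
        eps = eps_min + (1.0 - eps_min) * np.random.random()
        cos_t = 1.0 - (1.0 / eps - 1.0) / k
        sin2 = 1.0 - cos_t * cos_t
        g = eps + 1.0 / eps - sin2
        if np.random.random() * bound <= g:
            return eps, cos_t


@njit(cache=True)
def _transport_photon(
    x, y, z, dx, dy, dz, e_kev,
    density, material, nx, ny, nz, h,
    att_loge, log_mu, cum_pe, cum_inc,
    cutoff_kev,
    dose, events,
):
    """Transport one photon; returns (deposited, escaped) keV."""
    deposited = 0.0
    mec2 = 510.99895
    while True:
        if e_kev <= cutoff_kev:
            idx = _voxel_index(x, y, z, h, nx, ny, nz)
            if idx < 0:
                return deposited, e_kev
            dose[idx] += e_kev
            events[idx] += 1
            return deposited + e_kev, 0.0
        loge = np.log(e_kev)
        tau_target = -np.log(np.random.random())
        tau = 0.0
        interacted = False
        while True:
            idx = _voxel_index(x, y, z, h, nx, ny, nz)
            if idx < 0:
                return deposited, e_kev
            m = material[idx]
            mu_mm = np.exp(_loglin(att_loge, log_mu[m], loge)) * density[idx] * 0.1
            t_exit = _boundary_distance(x, y, z, dx, dy, dz, h)
            dtau = mu_mm * t_exit
            if tau + dtau >= tau_target and mu_mm > 0.0:
                t_int = (tau_target - tau) / mu_mm
                x += t_int * dx
                y += t_int * dy
                z += t_int * dz
                interacted = True
                break
            tau += dtau
            x += t_exit * dx
            y += t_exit * dy
            z += t_exit * dz
        if not interacted:
            return deposited, e_kev
        idx = _voxel_index(x, y, z, h, nx, ny, nz)
        if idx < 0:
            return deposited, e_kev
        m = material[idx]
        u = np.random.random()
        f_pe = _loglin(att_loge, cum_pe[m], loge)
        f_inc = _loglin(att_loge, cum_inc[m], loge)
        if u < f_pe:
            dose[idx] += e_kev
            events[idx] += 1
            return deposited + e_kev, 0.0
        elif u < f_inc:
            eps, cos_t = _sample_compton(e_kev / mec2)
            recoil = e_kev * (1.0 - eps)
            dose[idx] += recoil
            events[idx] += 1
            deposited += recoil
            e_kev *= eps
            phi = 2.0 * np.pi * np.random.random()
            dx, dy, dz = _rotate(dx, dy, dz, cos_t, phi)
        else:
            # coherent: Thomson-like angular redistribution, no energy loss
            while True:
                c = 2.0 * np.random.random() - 1.0
                if np.random.random() <= 0.5 * (1.0 + c * c):
                    break
            phi = 2.0 * np.pi * np.random.random()
            dx, dy, dz = _rotate(dx, dy, dz, c, phi)


@njit(cache=True)
def _run_batch(
    seed, n_hist,
    src_cdf, density, material, nx, ny, nz, h,
    photon_e, photon_y, elec_e, elec_y, beta_y, beta_icdf,
    att_loge, log_mu, cum_pe, cum_inc,
    er_loge, er_logr,
    cutoff_kev, range_cut_mm,
    dose, events,
):
    """Simulate ``n_hist`` primary decays; returns the energy ledger."""
    np.random.seed(seed)
    emitted = 0.0
    deposited = 0.0
    escaped = 0.0
    n_icdf = beta_icdf.shape[1]
    for _ in range(n_hist):
        r = np.random.random()
        vox = np.searchsorted(src_cdf, r)
        if vox >= src_cdf.shape[0]:
            vox = src_cdf.shape[0] - 1
        iz = vox % nz
        iy = (vox // nz) % ny
        ix = vox // (ny * nz)
        x0 = (ix + np.random.random()) * h
        y0 = (iy + np.random.random()) * h
        z0 = (iz + np.random.random()) * h
        # discrete electron lines
        for i in range(elec_e.shape[0]):
            y_int = int(elec_y[i])
            n_emit = y_int + (1 if np.random.random() < elec_y[i] - y_int else 0)
            for _k in range(n_emit):
                dx, dy, dz = _isotropic()
                emitted += elec_e[i]
                dep, esc = _deposit_electron(
                    x0, y0, z0, dx, dy, dz, elec_e[i],
                    density, nx, ny, nz, h, er_loge, er_logr, range_cut_mm,
                    dose, events,
                )
                deposited += dep
                escaped += esc
        # beta branches
        for i in range(beta_y.shape[0]):
            if np.random.random() < beta_y[i]:
                u = np.random.random() * (n_icdf - 1)
                j = int(u)
                if j > n_icdf - 2:
                    j = n_icdf - 2
                e_b = beta_icdf[i, j] + (u - j) * (beta_icdf[i, j + 1] - beta_icdf[i, j])
                if e_b < 1.0:
                    e_b = 1.0
                dx, dy, dz = _isotropic()
                emitted += e_b
                dep, esc = _deposit_electron(
                    x0, y0, z0, dx, dy, dz, e_b,
                    density, nx, ny, nz, h, er_loge, er_logr, range_cut_mm,
                    dose, events,
                )
                deposited += dep
                escaped += esc
        # photon lines
        for i in range(photon_e.shape[0]):
            y_int = int(photon_y[i])
            n_emit = y_int + (1 if np.random.random() < photon_y[i] - y_int else 0)
            for _k in range(n_emit):
                dx, dy, dz = _isotropic()
                emitted += photon_e[i]
                dep, esc = _transport_photon(
                    x0, y0, z0, dx, dy, dz, photon_e[i],
                    density, material, nx, ny, nz, h,
                    att_loge, log_mu, cum_pe, cum_inc, cutoff_kev,
                    dose, events,
                )
                deposited += dep
                escaped += esc
    return emitted, deposited, escaped
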