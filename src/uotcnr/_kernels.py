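"""Numba kernels for weighted Monte-Carlo photon transport.

Scattering-only step sampling with continuous absorption weighting; the
absorbing inclusion and the ultrasound voxel are axis-aligned boxes handled by
analytic segment clipping, so absorption is exact per region and the in-voxel
geometric path is accumulated per packet.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["transport_kernel", "transport_kernel_paired", "hg_sample_kernel"]


@njit(cache=True, inline="always")
def _slab_overlap(p0, p1, p2, u0, u1, u2, t_end, lo, hi):
    """Length of the segment p + t*u, t in [0, t_end], inside the box."""
    tmin = 0.0
    tmax = t_end
    p = (p0, p1, p2)
    u = (u0, u1, u2)
    for i in range(3):
        ui = u[i]
        if -1e-12 < ui < 1e-12:
            if p[i] < lo[i] or p[i] > hi[i]:
                return 0.0
        else:
            t1 = (lo[i] - p[i]) / ui
            t2 = (hi[i] - p[i]) / ui
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
            if tmin >= tmax:
                return 0.0
    return tmax - tmin


@njit(cache=True)
def hg_sample_kernel(g, n, seed):
    """n Henyey-Greenstein cos(theta) samples."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        if g != 0.0:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
            ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        else:
            ct = 2.0 * np.random.random() - 1.0
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        out[i] = ct
    return out


@njit(cache=True)
def transport_kernel(
    n_packets,
    seed,
    mu_s,
    g,
    mu_a_bg,
    mu_a_incl,
    incl_lo,
    incl_hi,
    vox_lo,
    vox_hi,
    src_cx,
    src_cy,
    src_hw,
    det_cx,
    det_cy,
    det_hw,
    half_x,
    half_y,
    depth_z,
    w_thresh,
    survive_p,
    max_steps,
):
    """Trace ``n_packets`` packets; return detected records and weight sinks.

    Returns (exit_x, exit_y, weight, path_in_voxel) for packets exiting the
    surface inside the detection aperture, plus (absorbed, escaped_elsewhere,
    total_reflected) weight sums.  Russian-roulette weight adjustments are
    folded into the absorbed sum so that detected + escaped + absorbed equals
    the launched weight to floating-point roundoff on every run.
    """
    np.random.seed(seed)
    det_x = np.empty(n_packets)
    det_y = np.empty(n_packets)
    det_w = np.empty(n_packets)
    det_l = np.empty(n_packets)
    n_det = 0
    absorbed = 0.0
    escaped = 0.0
    reflected_total = 0.0

    for _ in range(n_packets):
        px = src_cx + (2.0 * np.random.random() - 1.0) * src_hw
        py = src_cy + (2.0 * np.random.random() - 1.0) * src_hw
        pz = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        lvox = 0.0
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > max_steps:
                absorbed += w
                alive = False
                break
            if mu_s > 0.0:
                s = -np.log(np.random.random()) / mu_s
            else:
                s = 1.0e9
            # clip the step against the medium boundaries
            t_bound = s
            exit_code = 0
            if uz < 0.0:
                t = -pz / uz
                if t < t_bound:
                    t_bound = t
                    exit_code = 1
            elif uz > 0.0:
                t = (depth_z - pz) / uz
                if t < t_bound:
                    t_bound = t
                    exit_code = 2
            if ux > 0.0:
                t = (half_x - px) / ux
            elif ux < 0.0:
                t = (-half_x - px) / ux
            else:
                t = 1.0e18
            if t < t_bound:
                t_bound = t
                exit_code = 2
            if uy > 0.0:
                t = (half_y - py) / uy
            elif uy < 0.0:
                t = (-half_y - py) / uy
            else:
                t = 1.0e18
            if t < t_bound:
                t_bound = t
                exit_code = 2

            l_incl = _slab_overlap(px, py, pz, ux, uy, uz, t_bound, incl_lo, incl_hi)
            l_v = _slab_overlap(px, py, pz, ux, uy, uz, t_bound, vox_lo, vox_hi)
            decay = np.exp(-(mu_a_bg * (t_bound - l_incl) + mu_a_incl * l_incl))
            absorbed += w * (1.0 - decay)
            w *= decay
            lvox += l_v
            px += ux * t_bound
            py += uy * t_bound
            pz += uz * t_bound

            if exit_code == 1:
                reflected_total += w
                if abs(px - det_cx) <= det_hw and abs(py - det_cy) <= det_hw:
                    det_x[n_det] = px
                    det_y[n_det] = py
                    det_w[n_det] = w
                    det_l[n_det] = lvox
                    n_det += 1
                else:
                    escaped += w
                alive = False
            elif exit_code == 2:
                escaped += w
                alive = False
            else:
                # Henyey-Greenstein deflection
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    ct = 2.0 * np.random.random() - 1.0
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi)
                sp = np.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_new = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_new = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_new = -den * st * cp + uz * ct
                    norm = np.sqrt(ux_new * ux_new + uy_new * uy_new + uz_new * uz_new)
                    ux = ux_new / norm
                    uy = uy_new / norm
                    uz = uz_new / norm
                # Russian roulette below the weight threshold
                if w < w_thresh:
                    if np.random.random() < survive_p:
                        absorbed -= w * (1.0 / survive_p - 1.0)
                        w /= survive_p
                    else:
                        absorbed += w
                        alive = False

    return (
        det_x[:n_det].copy(),
        det_y[:n_det].copy(),
        det_w[:n_det].copy(),
        det_l[:n_det].copy(),
        absorbed,
        escaped,
        reflected_total,
    )


@njit(cache=True)
def transport_kernel_paired(
    n_packets,
    seed,
    mu_s,
    g,
    mu_a_bg,
    mu_a_incl,
    incl_lo,
    incl_hi,
    voxA_lo,
    voxA_hi,
    voxB_lo,
    voxB_hi,
    src_cx,
    src_cy,
    src_hw,
    det_cx,
    det_cy,
    det_hw,
    half_x,
    half_y,
    depth_z,
    w_thresh,
    survive_p,
    max_steps,
):
    """Like :func:`transport_kernel` but scoring both ultrasound voxel
    positions (A and B) along the same photon paths in a single pass, the
    exact common-random-numbers estimator for the A-B tagged difference."""
    np.random.seed(seed)
    det_x = np.empty(n_packets)
    det_y = np.empty(n_packets)
    det_w = np.empty(n_packets)
    det_lA = np.empty(n_packets)
    det_lB = np.empty(n_packets)
    n_det = 0
    absorbed = 0.0
    escaped = 0.0
    reflected_total = 0.0

    for _ in range(n_packets):
        px = src_cx + (2.0 * np.random.random() - 1.0) * src_hw
        py = src_cy + (2.0 * np.random.random() - 1.0) * src_hw
        pz = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        lA = 0.0
        lB = 0.0
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > max_steps:
                absorbed += w
                alive = False
                break
            if mu_s > 0.0:
                s = -np.log(np.random.random()) / mu_s
            else:
                s = 1.0e9
            t_bound = s
            exit_code = 0
            if uz < 0.0:
                t = -pz / uz
                if t < t_bound:
                    t_bound = t
                    exit_code = 1
            elif uz > 0.0:
                t = (depth_z - pz) / uz
                if t < t_bound:
                    t_bound = t
                    exit_code = 2
            if ux > 0.0:
                t = (half_x - px) / ux
            elif ux < 0.0:
                t = (-half_x - px) / ux
            else:
                t = 1.0e18
            if t < t_bound:
                t_bound = t
                exit_code = 2
            if uy > 0.0:
                t = (half_y - py) / uy
            elif uy < 0.0:
                t = (-half_y - py) / uy
            else:
                t = 1.0e18
            if t < t_bound:
                t_bound = t
                exit_code = 2

            l_incl = _slab_overlap(px, py, pz, ux, uy, uz, t_bound, incl_lo, incl_hi)
            lA += _slab_overlap(px, py, pz, ux, uy, uz, t_bound, voxA_lo, voxA_hi)
            lB += _slab_overlap(px, py, pz, ux, uy, uz, t_bound, voxB_lo, voxB_hi)
            decay = np.exp(-(mu_a_bg * (t_bound - l_incl) + mu_a_incl * l_incl))
            absorbed += w * (1.0 - decay)
            w *= decay
            px += ux * t_bound
            py += uy * t_bound
            pz += uz * t_bound

            if exit_code == 1:
                reflected_total += w
                if abs(px - det_cx) <= det_hw and abs(py - det_cy) <= det_hw:
                    det_x[n_det] = px
                    det_y[n_det] = py
                    det_w[n_det] = w
                    det_lA[n_det] = lA
                    det_lB[n_det] = lB
                    n_det += 1
                else:
                    escaped += w
                alive = False
            elif exit_code == 2:
                escaped += w
                alive = False
            else:
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    ct = 2.0 * np.random.random() - 1.0
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi)
                sp = np.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_new = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_new = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_new = -den * st * cp + uz * ct
                    norm = np.sqrt(ux_new * ux_new + uy_new * uy_new + uz_new * uz_new)
                    ux = ux_new / norm
                    uy = uy_new / norm
                    uz = uz_new / norm
                if w < w_thresh:
                    if np.random.random() < survive_p:
                        absorbed -= w * (1.0 / survive_p - 1.0)
                        w /= survive_p
                    else:
                        absorbed += w
                        alive = False

    return (
        det_x[:n_det].copy(),
        det_y[:n_det].copy(),
        det_w[:n_det].copy(),
        det_lA[:n_det].copy(),
        det_lB[:n_det].copy(),
        absorbed,
        escaped,
        reflected_total,
    )
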