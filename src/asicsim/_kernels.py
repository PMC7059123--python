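"""Numba forward-Euler integration kernels.

The integration scheme is deliberately plain explicit Euler with a constant
time step (the scheme the model was built and validated with); the kernels
add a per-step stability guard on the ASIC gate rates (dt*r must stay below
one) and a blow-up guard on the membrane potential.

Status codes returned by the kernels:
    -1           success
    k >= 0       membrane-potential blow-up at step k (|Vm| > 200 mV)
    -(k + 2)     ASIC rate stability violation (dt * r >= 1) at step k
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = -1


@njit(cache=True, inline="always")
def steady_state_scalar(p, ph):
    # p = (K, H, F, delta)
    return 1.0 / (1.0 + p[0] ** p[2] * 10.0 ** (p[2] * p[1] * (ph - 7.0 - p[3])))


@njit(cache=True, inline="always")
def rate_scalar(p, ph):
    # p = (a1, b1, c1, a2, b2, c2)
    return p[0] / (1.0 + np.exp(p[1] * (ph - p[2]))) + p[3] / (
        1.0 + np.exp(p[4] * (ph - p[5]))
    )


@njit(cache=True, inline="always")
def alpha_m(v):
    # v is membrane potential relative to -60 mV (plus any gate shift)
    u = 2.5 - 0.1 * v
    if abs(u) < 1e-6:
        return 1.0 - 0.5 * u  # removable singularity: u/(e^u - 1) -> 1
    return u / np.expm1(u)


@njit(cache=True, inline="always")
def beta_m(v):
    return 4.0 * np.exp(-v / 18.0)


@njit(cache=True, inline="always")
def alpha_h(v):
    return 0.007 * np.exp(-v / 20.0)


@njit(cache=True, inline="always")
def beta_h(v):
    return 0.1 / (1.0 + np.exp(3.0 - 0.1 * v))


@njit(cache=True, inline="always")
def alpha_n(v):
    w = 1.0 - 0.1 * v
    if abs(w) < 1e-6:
        return 0.1 * (1.0 - 0.5 * w)
    return 0.1 * w / np.expm1(w)


@njit(cache=True, inline="always")
def beta_n(v):
    return 0.125 * np.exp(-v / 80.0)


@njit(cache=True)
def voltage_clamp_kernel(ph, dt, vm, act_ss, act_rt, sens_ss, sens_rt,
                         g, e_rev, a0, s0, out_i, out_a, out_s):
    """Integrate the two ASIC gates under clamped Vm along a pH time course.

    ``ph`` holds the pH at each grid time; currents and gate values are
    recorded at grid times before each Euler update.
    """
    n = ph.shape[0]
    a = a0
    s = s0
    for k in range(n):
        p = ph[k]
        out_i[k] = g * a * s * (vm - e_rev)
        out_a[k] = a
        out_s[k] = s
        if k < n - 1:
            ra = rate_scalar(act_rt, p)
            rs = rate_scalar(sens_rt, p)
            if ra * dt >= 1.0 or rs * dt >= 1.0:
                return -(k + 2)
            a += dt * ra * (steady_state_scalar(act_ss, p) - a)
            s += dt * rs * (steady_state_scalar(sens_ss, p) - s)
    return STATUS_OK


@njit(cache=True)
def current_clamp_kernel(ph, dt, pr, act_ss, act_rt, sens_ss, sens_rt, y0,
                         out_v, out_cur, out_gate, record_aux):
    """Integrate the full six-variable neuron (Vm, m, h, n, a, s).

    ``pr`` packs the scalar neuron parameters:
    (c_m, g_na, g_k, g_l, e_na, e_k, e_l, i_stim, g_asic, e_asic,
     s_m, f_m, s_h, f_h).
    ``out_cur`` rows: I_Na, I_K, I_L, I_ASIC; ``out_gate`` rows: m, h, n, a, s.
    """
    c_m, g_na, g_k, g_l = pr[0], pr[1], pr[2], pr[3]
    e_na, e_k, e_l, i_stim = pr[4], pr[5], pr[6], pr[7]
    g_asic, e_asic = pr[8], pr[9]
    s_m, f_m, s_h, f_h = pr[10], pr[11], pr[12], pr[13]

    v = y0[0]
    m = y0[1]
    h = y0[2]
    nn = y0[3]
    a = y0[4]
    s = y0[5]
    n = ph.shape[0]
    for k in range(n):
        p = ph[k]
        i_na = g_na * m * m * m * h * (v - e_na)
        i_k = g_k * nn * nn * nn * nn * (v - e_k)
        i_l = g_l * (v - e_l)
        i_asic = g_asic * a * s * (v - e_asic)
        out_v[k] = v
        if record_aux:
            out_cur[0, k] = i_na
            out_cur[1, k] = i_k
            out_cur[2, k] = i_l
            out_cur[3, k] = i_asic
            out_gate[0, k] = m
            out_gate[1, k] = h
            out_gate[2, k] = nn
            out_gate[3, k] = a
            out_gate[4, k] = s
        if k < n - 1:
            if abs(v) > 200.0:
                return k
            ra = rate_scalar(act_rt, p)
            rs = rate_scalar(sens_rt, p)
            if ra * dt >= 1.0 or rs * dt >= 1.0:
                return -(k + 2)
            vm_m = v - s_m + 60.0
            vm_h = v - s_h + 60.0
            vn = v + 60.0
            am = f_m * alpha_m(vm_m)
            bm = f_m * beta_m(vm_m)
            ah = f_h * alpha_h(vm_h)
            bh = f_h * beta_h(vm_h)
            an = alpha_n(vn)
            bn = beta_n(vn)
            v += dt * (-(i_na + i_k + i_l + i_asic + i_stim) / c_m)
            m += dt * (am * (1.0 - m) - bm * m)
            h += dt * (ah * (1.0 - h) - bh * h)
            nn += dt * (an * (1.0 - nn) - bn * nn)
            a += dt * ra * (steady_state_scalar(act_ss, p) - a)
            s += dt * rs * (steady_state_scalar(sens_ss, p) - s)
    return STATUS_OK
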