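"""Compiled batch forward-Euler kernels, one per model.

All kernels share the same contract:

``kernel(states, params, istim, dt, record_start, stride, out, valid)``

* ``states``: (P, state_dim) float64, advanced in place to the final state.
* ``params``: (P, n_parameters) float64, one full parameter vector per row.
* ``istim``: per-step stimulus current (1/ms), length = total step count.
* the voltage of particle p is recorded into ``out[p, m]`` at steps
  ``record_start + m * stride`` (the state *before* the Euler update at that
  step, i.e. the sample at time t reflects the solution at t).
* ``valid[p]`` is cleared when a particle's state goes non-finite or runs
  away (|u| > 1e3); its state is then zeroed so the rest of the batch keeps
  vector speed, and downstream fitness treats the trace as worst-case.

Performance notes, relevant because these loops dominate every fit:

* loops run time-outer / particle-inner over contiguous per-variable
  arrays so LLVM can vectorize across the independent particles;
* per-particle reciprocal time constants are hoisted out of the time loop;
* state variables are flushed to zero below 1e-280: voltages of
  sub-threshold particles decay exponentially for hundreds of
  milliseconds, and letting them enter the denormal range stalls the
  whole SIMD batch by an order of magnitude;
* kernels are cached on disk to amortize JIT cost.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SIG = "void(f8[:,::1], f8[:,::1], f8[::1], f8, i8, i8, f8[:,::1], b1[::1])"
# strict IEEE semantics: the in-loop validity checks rely on isfinite, which
# fast-math's no-NaN assumption would fold away
_JIT = dict(cache=True, nogil=True)

_TINY = 1e-280  # flush-to-zero threshold (far below any physical voltage)


@njit(inline="always")
def _ftz(x):
    # written so NaN/inf pass through untouched (NaN comparisons are false)
    # and only genuine denormal-range magnitudes are flushed
    return 0.0 if abs(x) < _TINY else x


@njit(_SIG, **_JIT)
def ms_kernel(states, params, istim, dt, record_start, stride, out, valid):
    P = states.shape[0]
    n_steps = istim.shape[0]
    u = np.empty(P)
    h = np.empty(P)
    inv_tin = np.empty(P)
    inv_tout = np.empty(P)
    inv_topen = np.empty(P)
    inv_tclose = np.empty(P)
    vg = np.empty(P)
    for p in range(P):
        u[p] = states[p, 0]
        h[p] = states[p, 1]
        inv_tin[p] = 1.0 / params[p, 0]
        inv_tout[p] = 1.0 / params[p, 1]
        inv_topen[p] = 1.0 / params[p, 2]
        inv_tclose[p] = 1.0 / params[p, 3]
        vg[p] = params[p, 4]
    m = 0
    next_rec = record_start
    for step in range(n_steps):
        if step == next_rec:
            for p in range(P):
                if not (math.isfinite(u[p]) and math.isfinite(h[p]) and abs(u[p]) < 1e3):
                    valid[p] = False
                    u[p] = 0.0
                    h[p] = 0.0
                out[p, m] = u[p]
            m += 1
            next_rec += stride
        s = istim[step]
        for p in range(P):
            up = u[p]
            hp = h[p]
            du = hp * up * up * (1.0 - up) * inv_tin[p] - up * inv_tout[p] + s
            dh = -hp * inv_tclose[p] if up >= vg[p] else (1.0 - hp) * inv_topen[p]
            u[p] = _ftz(up + dt * du)
            h[p] = _ftz(hp + dt * dh)
    for p in range(P):
        states[p, 0] = u[p]
        states[p, 1] = h[p]


@njit(_SIG, **_JIT)
def mms_kernel(states, params, istim, dt, record_start, stride, out, valid):
    P = states.shape[0]
    n_steps = istim.shape[0]
    u = np.empty(P)
    h = np.empty(P)
    inv_tin = np.empty(P)
    inv_tout = np.empty(P)
    inv_topen = np.empty(P)
    inv_tclose = np.empty(P)
    vg = np.empty(P)
    for p in range(P):
        u[p] = states[p, 0]
        h[p] = states[p, 1]
        inv_tin[p] = 1.0 / params[p, 0]
        inv_tout[p] = 1.0 / params[p, 1]
        inv_topen[p] = 1.0 / params[p, 2]
        inv_tclose[p] = 1.0 / params[p, 3]
        vg[p] = params[p, 4]
    m = 0
    next_rec = record_start
    for step in range(n_steps):
        if step == next_rec:
            for p in range(P):
                if not (math.isfinite(u[p]) and math.isfinite(h[p]) and abs(u[p]) < 1e3):
                    valid[p] = False
                    u[p] = 0.0
                    h[p] = 0.0
                out[p, m] = u[p]
            m += 1
            next_rec += stride
        s = istim[step]
        for p in range(P):
            up = u[p]
            hp = h[p]
            du = (
                hp * up * (up - vg[p]) * (1.0 - up) * inv_tin[p]
                - (1.0 - hp) * up * inv_tout[p]
                + s
            )
            dh = -hp * inv_tclose[p] if up >= vg[p] else (1.0 - hp) * inv_topen[p]
            u[p] = _ftz(up + dt * du)
            h[p] = _ftz(hp + dt * dh)
    for p in range(P):
        states[p, 0] = u[p]
        states[p, 1] = h[p]


@njit(_SIG, **_JIT)
def mfhn_kernel(states, params, istim, dt, record_start, stride, out, valid):
    P = states.shape[0]
    n_steps = istim.shape[0]
    u = np.empty(P)
    v = np.empty(P)
    a = np.empty(P)
    b = np.empty(P)
    c1 = np.empty(P)
    c2 = np.empty(P)
    d = np.empty(P)
    for p in range(P):
        u[p] = states[p, 0]
        v[p] = states[p, 1]
        a[p] = params[p, 0]
        b[p] = params[p, 1]
        c1[p] = params[p, 2]
        c2[p] = params[p, 3]
        d[p] = params[p, 4]
    m = 0
    next_rec = record_start
    for step in range(n_steps):
        if step == next_rec:
            for p in range(P):
                if not (math.isfinite(u[p]) and math.isfinite(v[p]) and abs(u[p]) < 1e3):
                    valid[p] = False
                    u[p] = 0.0
                    v[p] = 0.0
                out[p, m] = u[p]
            m += 1
            next_rec += stride
        s = istim[step]
        for p in range(P):
            up = u[p]
            vp = v[p]
            du = c1[p] * up * (up - a[p]) * (1.0 - up) - c2[p] * up * vp + s
            dv = b[p] * (up - d[p] * vp)
            u[p] = _ftz(up + dt * du)
            v[p] = _ftz(vp + dt * dv)
    for p in range(P):
        states[p, 0] = u[p]
        states[p, 1] = v[p]


@njit(_SIG, **_JIT)
def fk_kernel(states, params, istim, dt, record_start, stride, out, valid):
    P = states.shape[0]
    n_steps = istim.shape[0]
    u = np.empty(P)
    v = np.empty(P)
    w = np.empty(P)
    inv_td = np.empty(P)
    inv_tr = np.empty(P)
    inv_2tsi = np.empty(P)
    inv_t0 = np.empty(P)
    inv_tvp = np.empty(P)
    inv_tv1m = np.empty(P)
    inv_tv2m = np.empty(P)
    inv_twp = np.empty(P)
    inv_twm = np.empty(P)
    u_c = np.empty(P)
    u_v = np.empty(P)
    u_csi = np.empty(P)
    kk = np.empty(P)
    for p in range(P):
        u[p] = states[p, 0]
        v[p] = states[p, 1]
        w[p] = states[p, 2]
        inv_td[p] = 1.0 / params[p, 0]
        inv_tr[p] = 1.0 / params[p, 1]
        inv_2tsi[p] = 0.5 / params[p, 2]
        inv_t0[p] = 1.0 / params[p, 3]
        inv_tvp[p] = 1.0 / params[p, 4]
        inv_tv1m[p] = 1.0 / params[p, 5]
        inv_tv2m[p] = 1.0 / params[p, 6]
        inv_twp[p] = 1.0 / params[p, 7]
        inv_twm[p] = 1.0 / params[p, 8]
        u_c[p] = params[p, 9]
        u_v[p] = params[p, 10]
        u_csi[p] = params[p, 11]
        kk[p] = params[p, 12]
    m = 0
    next_rec = record_start
    for step in range(n_steps):
        if step == next_rec:
            for p in range(P):
                ok = (
                    math.isfinite(u[p])
                    and math.isfinite(v[p])
                    and math.isfinite(w[p])
                    and abs(u[p]) < 1e3
                )
                if not ok:
                    valid[p] = False
                    u[p] = 0.0
                    v[p] = 0.0
                    w[p] = 0.0
                out[p, m] = u[p]
            m += 1
            next_rec += stride
        s = istim[step]
        for p in range(P):
            up = u[p]
            vp = v[p]
            wp = w[p]
            if up >= u_c[p]:
                j_fi = -vp * (1.0 - up) * (up - u_c[p]) * inv_td[p]
                j_so = inv_tr[p]
                dv = -vp * inv_tvp[p]
                dw = -wp * inv_twp[p]
            else:
                j_fi = 0.0
                j_so = up * inv_t0[p]
                inv_tvm = inv_tv1m[p] if up >= u_v[p] else inv_tv2m[p]
                dv = (1.0 - vp) * inv_tvm
                dw = (1.0 - wp) * inv_twm[p]
            j_si = -wp * (1.0 + math.tanh(kk[p] * (up - u_csi[p]))) * inv_2tsi[p]
            du = -(j_fi + j_so + j_si) + s
            u[p] = _ftz(up + dt * du)
            v[p] = _ftz(vp + dt * dv)
            w[p] = _ftz(wp + dt * dw)
    for p in range(P):
        states[p, 0] = u[p]
        states[p, 1] = v[p]
        states[p, 2] = w[p]


@njit(_SIG, **_JIT)
def bocf_kernel(states, params, istim, dt, record_start, stride, out, valid):
    P = states.shape[0]
    n_steps = istim.shape[0]
    u = np.ascontiguousarray(states[:, 0].copy())
    v = np.ascontiguousarray(states[:, 1].copy())
    w = np.ascontiguousarray(states[:, 2].copy())
    s = np.ascontiguousarray(states[:, 3].copy())
    m = 0
    next_rec = record_start
    for step in range(n_steps):
        if step == next_rec:
            for p in range(P):
                ok = (
                    math.isfinite(u[p])
                    and math.isfinite(v[p])
                    and math.isfinite(w[p])
                    and math.isfinite(s[p])
                    and abs(u[p]) < 1e3
                )
                if not ok:
                    valid[p] = False
                    u[p] = 0.0
                    v[p] = 0.0
                    w[p] = 0.0
                    s[p] = 0.0
                out[p, m] = u[p]
            m += 1
            next_rec += stride
        stim = istim[step]
        for p in range(P):
            up = u[p]
            vp = v[p]
            wp = w[p]
            sp = s[p]
            u_u = params[p, 0]
            theta_v = params[p, 1]
            theta_w = params[p, 2]
            theta_vm = params[p, 3]
            theta_o = params[p, 4]
            tau_v1m = params[p, 5]
            tau_v2m = params[p, 6]
            tau_vp = params[p, 7]
            tau_w1m = params[p, 8]
            tau_w2m = params[p, 9]
            k_wm = params[p, 10]
            u_wm = params[p, 11]
            tau_wp = params[p, 12]
            tau_fi = params[p, 13]
            tau_o1 = params[p, 14]
            tau_o2 = params[p, 15]
            tau_so1 = params[p, 16]
            tau_so2 = params[p, 17]
            k_so = params[p, 18]
            u_so = params[p, 19]
            tau_s1 = params[p, 20]
            tau_s2 = params[p, 21]
            k_s = params[p, 22]
            u_s = params[p, 23]
            tau_si = params[p, 24]
            tau_winf = params[p, 25]
            w_infstar = params[p, 26]

            hv = 1.0 if up >= theta_v else 0.0
            hw = 1.0 if up >= theta_w else 0.0
            hvm = 1.0 if up >= theta_vm else 0.0
            ho = 1.0 if up >= theta_o else 0.0
            tau_vm = tau_v2m if hvm == 1.0 else tau_v1m
            tau_wm = tau_w1m + (tau_w2m - tau_w1m) * (
                1.0 + math.tanh(k_wm * (up - u_wm))
            ) * 0.5
            tau_so = tau_so1 + (tau_so2 - tau_so1) * (
                1.0 + math.tanh(k_so * (up - u_so))
            ) * 0.5
            tau_s = tau_s2 if hw == 1.0 else tau_s1
            tau_o = tau_o2 if ho == 1.0 else tau_o1
            v_inf = 0.0 if hvm == 1.0 else 1.0
            w_inf = w_infstar if ho == 1.0 else 1.0 - up / tau_winf
            j_fi = -vp * hv * (up - theta_v) * (u_u - up) / tau_fi
            j_so = up * (1.0 - hw) / tau_o + hw / tau_so
            j_si = -hw * wp * sp / tau_si
            du = -(j_fi + j_so + j_si) + stim
            dv = (1.0 - hv) * (v_inf - vp) / tau_vm - hv * vp / tau_vp
            dw = (1.0 - hw) * (w_inf - wp) / tau_wm - hw * wp / tau_wp
            ds = ((1.0 + math.tanh(k_s * (up - u_s))) * 0.5 - sp) / tau_s
            u[p] = _ftz(up + dt * du)
            v[p] = _ftz(vp + dt * dv)
            w[p] = _ftz(wp + dt * dw)
            s[p] = _ftz(sp + dt * ds)
    for p in range(P):
        states[p, 0] = u[p]
        states[p, 1] = v[p]
        states[p, 2] = w[p]
        states[p, 3] = s[p]


@njit(_SIG, **_JIT)
def bbocf_kernel(states, params, istim, dt, record_start, stride, out, valid):
    P = states.shape[0]
    n_steps = istim.shape[0]
    u = np.ascontiguousarray(states[:, 0].copy())
    v = np.ascontiguousarray(states[:, 1].copy())
    w = np.ascontiguousarray(states[:, 2].copy())
    s = np.ascontiguousarray(states[:, 3].copy())
    m = 0
    next_rec = record_start
    for step in range(n_steps):
        if step == next_rec:
            for p in range(P):
                ok = (
                    math.isfinite(u[p])
                    and math.isfinite(v[p])
                    and math.isfinite(w[p])
                    and math.isfinite(s[p])
                    and abs(u[p]) < 1e3
                )
                if not ok:
                    valid[p] = False
                    u[p] = 0.0
                    v[p] = 0.0
                    w[p] = 0.0
                    s[p] = 0.0
                out[p, m] = u[p]
            m += 1
            next_rec += stride
        stim = istim[step]
        for p in range(P):
            up = u[p]
            vp = v[p]
            wp = w[p]
            sp = s[p]
            u_u = params[p, 0]
            theta_v = params[p, 1]
            theta_w = params[p, 2]
            theta_vm = params[p, 3]
            theta_o = params[p, 4]
            tau_v1m = params[p, 5]
            tau_v2m = params[p, 6]
            tau_vp = params[p, 7]
            tau_w1m = params[p, 8]
            tau_w2m = params[p, 9]
            k_wm = params[p, 10]
            u_wm = params[p, 11]
            tau_fi = params[p, 12]
            tau_o1 = params[p, 13]
            tau_o2 = params[p, 14]
            tau_so1 = params[p, 15]
            tau_so2 = params[p, 16]
            k_so = params[p, 17]
            u_so = params[p, 18]
            tau_s1 = params[p, 19]
            tau_s2 = params[p, 20]
            k_s = params[p, 21]
            u_s = params[p, 22]
            tau_winf = params[p, 23]
            w_infstar = params[p, 24]
            # split time scales: tau_w+ blends on voltage, tau_si on the s gate
            tau_wp = params[p, 25] + (params[p, 26] - params[p, 25]) * (
                1.0 + math.tanh(params[p, 27] * (up - params[p, 28]))
            ) * 0.5
            tau_si = params[p, 29] + (params[p, 30] - params[p, 29]) * (
                1.0 + math.tanh(params[p, 31] * (sp - params[p, 32]))
            ) * 0.5

            hv = 1.0 if up >= theta_v else 0.0
            hw = 1.0 if up >= theta_w else 0.0
            hvm = 1.0 if up >= theta_vm else 0.0
            ho = 1.0 if up >= theta_o else 0.0
            tau_vm = tau_v2m if hvm == 1.0 else tau_v1m
            tau_wm = tau_w1m + (tau_w2m - tau_w1m) * (
                1.0 + math.tanh(k_wm * (up - u_wm))
            ) * 0.5
            tau_so = tau_so1 + (tau_so2 - tau_so1) * (
                1.0 + math.tanh(k_so * (up - u_so))
            ) * 0.5
            tau_s = tau_s2 if hw == 1.0 else tau_s1
            tau_o = tau_o2 if ho == 1.0 else tau_o1
            v_inf = 0.0 if hvm == 1.0 else 1.0
            w_inf = w_infstar if ho == 1.0 else 1.0 - up / tau_winf
            j_fi = -vp * hv * (up - theta_v) * (u_u - up) / tau_fi
            j_so = up * (1.0 - hw) / tau_o + hw / tau_so
            j_si = -hw * wp * sp / tau_si
            du = -(j_fi + j_so + j_si) + stim
            dv = (1.0 - hv) * (v_inf - vp) / tau_vm - hv * vp / tau_vp
            dw = (1.0 - hw) * (w_inf - wp) / tau_wm - hw * wp / tau_wp
            ds = ((1.0 + math.tanh(k_s * (up - u_s))) * 0.5 - sp) / tau_s
            u[p] = _ftz(up + dt * du)
            v[p] = _ftz(vp + dt * dv)
            w[p] = _ftz(wp + dt * dw)
            s[p] = _ftz(sp + dt * ds)
    for p in range(P):
        states[p, 0] = u[p]
        states[p, 1] = v[p]
        states[p, 2] = w[p]
        states[p, 3] = s[p]


KERNELS = {
    "MS": ms_kernel,
    "MMS": mms_kernel,
    "MFHN": mfhn_kernel,
    "FK": fk_kernel,
    "BOCF": bocf_kernel,
    "BBOCF": bbocf_kernel,
}
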