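"""Numba-compiled inner loops for the forward-Euler / Euler-Maruyama integrators.

These kernels are implementation detail: the public simulators in
:mod:`memhh.device`, :mod:`memhh.hh`, :mod:`memhh.hybrid` and
:mod:`memhh.axon` wrap them with parameter validation and trace packaging.
All kernels take parameter vectors in the fixed ordering of
``MemristorParams.as_array()`` / ``HHParams.as_array()`` and operate on
contiguous float64 arrays.  Voltage arguments of exp/sinh are clamped to
+-40 to avoid overflow on transiently diverging trajectories.
"""

import math

import numpy as np
from numba import njit

_LIMIT = 40.0


@njit(cache=True, fastmath=False)
def _cl(x):
    if x > _LIMIT:
        return _LIMIT
    if x < -_LIMIT:
        return -_LIMIT
    return x


@njit(cache=True)
def _dev_current(pm, w, V):
    # pm: tau, alpha, beta, gamma, delta, eta, lam, w_min, w_max
    s = (1.0 - w) * pm[1] * (1.0 - math.exp(-_cl(pm[2] * V)))
    t = w * pm[3] * math.sinh(_cl(pm[4] * V))
    return s + t


@njit(cache=True)
def _dev_current_linear(pm, w, V):
    return w * (pm[3] * pm[4] - pm[1] * pm[2]) * V + pm[1] * pm[2] * V


@njit(cache=True)
def _dev_rate(pm, w, V):
    win = 1.0 - math.exp(w - 3.0)
    return win * pm[6] * math.sinh(_cl(pm[5] * V)) - (w - pm[7]) / pm[0]


@njit(cache=True)
def device_state_kernel(V, dt, pm, w0):
    """State trajectory of the memristor under an applied voltage waveform."""
    n = V.size
    w = np.empty(n)
    w[0] = w0
    for k in range(n - 1):
        wn = w[k] + dt * _dev_rate(pm, w[k], V[k])
        if wn < pm[7]:
            wn = pm[7]
        elif wn > pm[8]:
            wn = pm[8]
        w[k + 1] = wn
    return w


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gate kinetics (canonical squid-axon rates, modern convention)

@njit(cache=True)
def _trap(x, y):
    # x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled in
    if abs(x / y) < 1e-6:
        return y + 0.5 * x
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def _alpha_n(V):
    return 0.01 * _trap(V + 55.0, 10.0)


@njit(cache=True)
def _beta_n(V):
    return 0.125 * math.exp(-(V + 65.0) / 80.0)


@njit(cache=True)
def _alpha_m(V):
    return 0.1 * _trap(V + 40.0, 10.0)


@njit(cache=True)
def _beta_m(V):
    return 4.0 * math.exp(-(V + 65.0) / 18.0)


@njit(cache=True)
def _alpha_h(V):
    return 0.07 * math.exp(-(V + 65.0) / 20.0)


@njit(cache=True)
def _beta_h(V):
    return 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))


@njit(cache=True)
def hh_kernel(iapp, dt, ph, V0, n0, m0, h0):
    """Full HH neuron. ph: Cm, gNa, gK, gL, ENa, EK, EL."""
    n_steps = iapp.size
    V = np.empty(n_steps)
    ng = np.empty(n_steps)
    mg = np.empty(n_steps)
    hg = np.empty(n_steps)
    V[0], ng[0], mg[0], hg[0] = V0, n0, m0, h0
    for k in range(n_steps - 1):
        v, n, m, h = V[k], ng[k], mg[k], hg[k]
        i_na = ph[1] * m * m * m * h * (v - ph[4])
        i_k = ph[2] * n * n * n * n * (v - ph[5])
        i_l = ph[3] * (v - ph[6])
        V[k + 1] = v + dt * (iapp[k] - i_na - i_k - i_l) / ph[0]
        n1 = n + dt * (_alpha_n(v) * (1.0 - n) - _beta_n(v) * n)
        m1 = m + dt * (_alpha_m(v) * (1.0 - m) - _beta_m(v) * m)
        h1 = h + dt * (_alpha_h(v) * (1.0 - h) - _beta_h(v) * h)
        ng[k + 1] = min(max(n1, 0.0), 1.0)
        mg[k + 1] = min(max(m1, 0.0), 1.0)
        hg[k + 1] = min(max(h1, 0.0), 1.0)
    return V, ng, mg, hg


@njit(cache=True)
def hybrid_kernel(iapp, dt, ph, pm, v_scale, t_scale, i_scale, linear_law,
                  V0, m0, h0, w0, v_guard):
    """HH neuron with the potassium branch replaced by the scaled memristor.

    Returns (V, m, h, w, abort_index); abort_index = -1 when the divergence
    guard |V| > v_guard never fired.
    """
    n_steps = iapp.size
    V = np.empty(n_steps)
    mg = np.empty(n_steps)
    hg = np.empty(n_steps)
    wg = np.empty(n_steps)
    V[0], mg[0], hg[0], wg[0] = V0, m0, h0, w0
    abort = -1
    for k in range(n_steps - 1):
        v, m, h, w = V[k], mg[k], hg[k], wg[k]
        vd = v_scale * (v - ph[5])  # device voltage, volts
        if linear_law:
            i_dev = _dev_current_linear(pm, w, vd)
        else:
            i_dev = _dev_current(pm, w, vd)
        i_k = i_scale * i_dev
        i_na = ph[1] * m * m * m * h * (v - ph[4])
        i_l = ph[3] * (v - ph[6])
        V[k + 1] = v + dt * (iapp[k] - i_na - i_k - i_l) / ph[0]
        m1 = m + dt * (_alpha_m(v) * (1.0 - m) - _beta_m(v) * m)
        h1 = h + dt * (_alpha_h(v) * (1.0 - h) - _beta_h(v) * h)
        mg[k + 1] = min(max(m1, 0.0), 1.0)
        hg[k + 1] = min(max(h1, 0.0), 1.0)
        w1 = w + dt * t_scale * _dev_rate(pm, w, vd)
        if w1 < pm[7]:
            w1 = pm[7]
        elif w1 > pm[8]:
            w1 = pm[8]
        wg[k + 1] = w1
        if abs(V[k + 1]) > v_guard and abort < 0:
            abort = k + 1
            break
    return V, mg, hg, wg, abort


@njit(cache=True)
def scaled_circuit_kernel(iapp_phys, dt_phys, cm_p, gna_p, rl_p, ena_p, ek_p, el_p,
                          pm, linear_law, V0, m0, h0, w0, t_scale, v_scale):
    """Physically re-scaled hybrid circuit, integrated in device units.

    State voltage in volts, currents in uA, physical time in ms.  The gate
    kinetics and the memristor clock still run in biological time, recovered
    as t_bio = t_phys * t_scale and v_bio = V_phys / v_scale.
    gna_p: sodium conductance in uA/V; rl_p: leak resistance in V/uA.
    """
    n_steps = iapp_phys.size
    V = np.empty(n_steps)
    mg = np.empty(n_steps)
    hg = np.empty(n_steps)
    wg = np.empty(n_steps)
    V[0], mg[0], hg[0], wg[0] = V0, m0, h0, w0
    for k in range(n_steps - 1):
        v, m, h, w = V[k], mg[k], hg[k], wg[k]
        vd = v - ek_p  # voltage across the memristor branch, volts
        if linear_law:
            i_k = _dev_current_linear(pm, w, vd)
        else:
            i_k = _dev_current(pm, w, vd)
        i_na = gna_p * m * m * m * h * (v - ena_p)
        i_l = (v - el_p) / rl_p
        V[k + 1] = v + dt_phys * (iapp_phys[k] - i_na - i_k - i_l) / cm_p
        v_bio = v / v_scale  # gates live on the biological voltage axis
        dt_bio = dt_phys / t_scale
        m1 = m + dt_bio * (_alpha_m(v_bio) * (1.0 - m) - _beta_m(v_bio) * m)
        h1 = h + dt_bio * (_alpha_h(v_bio) * (1.0 - h) - _beta_h(v_bio) * h)
        mg[k + 1] = min(max(m1, 0.0), 1.0)
        hg[k + 1] = min(max(h1, 0.0), 1.0)
        w1 = w + dt_phys * _dev_rate(pm, w, vd)
        if w1 < pm[7]:
            w1 = pm[7]
        elif w1 > pm[8]:
            w1 = pm[8]
        wg[k + 1] = w1
    return V, mg, hg, wg


@njit(cache=True)
def axon_kernel(iapp, dt, ph, pm, v_scale, t_scale, i_scale, linear_law,
                g_axial, V0, m0, h0, w0, v_guard):
    """Chain of hybrid compartments with nearest-neighbour resistive coupling.

    iapp: (n_steps,) stimulus into compartment 0 only.  Sealed ends.
    Returns (V[n_steps, ncomp], w[n_steps, ncomp], abort_index).
    """
    n_steps = iapp.size
    ncomp = V0.size
    V = np.empty((n_steps, ncomp))
    W = np.empty((n_steps, ncomp))
    m = m0.copy()
    h = h0.copy()
    w = w0.copy()
    v = V0.copy()
    V[0] = v
    W[0] = w
    abort = -1
    for k in range(n_steps - 1):
        vn = np.empty(ncomp)
        for j in range(ncomp):
            vj, mj, hj, wj = v[j], m[j], h[j], w[j]
            vd = v_scale * (vj - ph[5])
            if linear_law:
                i_dev = _dev_current_linear(pm, wj, vd)
            else:
                i_dev = _dev_current(pm, wj, vd)
            i_mem = i_scale * i_dev
            i_na = ph[1] * mj * mj * mj * hj * (vj - ph[4])
            i_l = ph[3] * (vj - ph[6])
            i_cpl = 0.0
            if j > 0:
                i_cpl += g_axial * (v[j - 1] - vj)
            if j < ncomp - 1:
                i_cpl += g_axial * (v[j + 1] - vj)
            i_in = iapp[k] if j == 0 else 0.0
            vn[j] = vj + dt * (i_in + i_cpl - i_na - i_mem - i_l) / ph[0]
            m1 = mj + dt * (_alpha_m(vj) * (1.0 - mj) - _beta_m(vj) * mj)
            h1 = hj + dt * (_alpha_h(vj) * (1.0 - hj) - _beta_h(vj) * hj)
            m[j] = min(max(m1, 0.0), 1.0)
            h[j] = min(max(h1, 0.0), 1.0)
            w1 = wj + dt * t_scale * _dev_rate(pm, wj, vd)
            if w1 < pm[7]:
                w1 = pm[7]
            elif w1 > pm[8]:
                w1 = pm[8]
            w[j] = w1
        v = vn
        V[k + 1] = v
        W[k + 1] = w
        if abort < 0:
            for j in range(ncomp):
                if abs(v[j]) > v_guard:
                    abort = k + 1
        if abort >= 0:
            break
    return V, W, abort


@njit(cache=True)
def reduced_model_kernel(on, dt, tau, A, G_min, G0):
    """Reduced write-pulse conductance model: dG/dt = -(G - G_min)/tau + A*on(t)."""
    n = on.size
    G = np.empty(n)
    G[0] = G0
    for k in range(n - 1):
        G[k + 1] = G[k] + dt * (-(G[k] - G_min) / tau + A * on[k])
    return G
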