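"""Numba time-stepping kernel for the branched-cable backward-Euler solver.

One compartment per segment; the linear system of the implicit voltage
update is solved exactly each step by Hines elimination on the tree
(parent index < child index), cost linear in compartment count.  Gates
are advanced by the exact exponential update at the segment's current
voltage before each voltage step (first-order staggered scheme).

Internal units: mV, ms, uS, nA, nF (so g[uS]*V[mV] = I[nA] and
C[nF]*dV/dt[mV/ms] = I[nA]).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_CURRENT = 0
MODE_VOLTAGE = 1


@njit(cache=True)
def _gate_updates(gs, m, h, V, dt, n_ch, n,
                  v12a, ka, tba, taa, tma, tsa,
                  has_h, v12h, kh, tbh, tah, tmh, tsh):
    for ch in range(n_ch):
        for i in range(n):
            v = V[i]
            # activation: increasing Boltzmann, sigmoid tau
            minf = 1.0 / (1.0 + np.exp((v12a[ch] - v) / ka[ch]))
            taum = tba[ch] + taa[ch] / (1.0 + np.exp((v - tma[ch]) / tsa[ch]))
            m[ch, i] += (minf - m[ch, i]) * (1.0 - np.exp(-dt / taum))
            if has_h[ch] == 1:
                hinf = 1.0 / (1.0 + np.exp((v - v12h[ch]) / kh[ch]))
                tauh = tbh[ch] + tah[ch] / (1.0 + np.exp((v - tmh[ch]) / tsh[ch]))
                h[ch, i] += (hinf - h[ch, i]) * (1.0 - np.exp(-dt / tauh))


@njit(cache=True)
def run_kernel(parent, gax, c_over_dt, gpas, epas,
               gs, p_pow, Ech,
               v12a, ka, tba, taa, tma, tsa,
               has_h, v12h, kh, tbh, tah, tmh, tsh,
               m, h, V, dt, n_steps,
               mode, stim, stim_idx, gclamp,
               rec_idx, gate_idx, order):
    """Advance the model n_steps; returns recorded traces.

    stim: per-step injected current (nA) in current-clamp mode or
    command voltage (mV) in voltage-clamp mode, applied at stim_idx.
    order selects the voltage update: 1 = backward Euler, 2 =
    Crank-Nicolson (trapezoid on membrane and axial currents; the
    clamp source term stays fully implicit for stability).
    Returns (vrec, irec, mrec, hrec): voltage at rec_idx, clamp/stim
    current (nA), and gate trajectories at gate_idx, each length
    n_steps + 1 (sample 0 is the initial condition).
    """
    n = V.shape[0]
    n_ch = gs.shape[0]
    d = np.empty(n)
    rhs = np.empty(n)
    gax_eff = gax.copy()
    theta = 1.0 if order == 1 else 0.5
    if order == 2:
        for i in range(n):
            gax_eff[i] = 0.5 * gax[i]

    vrec = np.empty(n_steps + 1)
    irec = np.zeros(n_steps + 1)
    mrec = np.empty((n_ch, n_steps + 1))
    hrec = np.empty((n_ch, n_steps + 1))
    vrec[0] = V[rec_idx]
    for ch in range(n_ch):
        mrec[ch, 0] = m[ch, gate_idx]
        hrec[ch, 0] = h[ch, gate_idx]

    for k in range(1, n_steps + 1):
        _gate_updates(gs, m, h, V, dt, n_ch, n,
                      v12a, ka, tba, taa, tma, tsa,
                      has_h, v12h, kh, tbh, tah, tmh, tsh)
        # assemble diagonal and right-hand side
        for i in range(n):
            gtot = gpas[i]
            gE = gpas[i] * epas[i]
            for ch in range(n_ch):
                gch = gs[ch, i]
                if gch > 0.0:
                    mm = m[ch, i]
                    mp = mm
                    for _ in range(p_pow[ch] - 1):
                        mp *= mm
                    gm = gch * mp
                    if has_h[ch] == 1:
                        gm *= h[ch, i]
                    gtot += gm
                    gE += gm * Ech[ch]
            d[i] = c_over_dt[i] + theta * gtot
            rhs[i] = (c_over_dt[i] - (1.0 - theta) * gtot) * V[i] + gE
        if mode == MODE_CURRENT:
            rhs[stim_idx] += stim[k]
        else:
            d[stim_idx] += gclamp
            rhs[stim_idx] += gclamp * stim[k]
        # axial coupling (explicit part of the trapezoid goes to the rhs)
        for i in range(1, n):
            d[i] += gax_eff[i]
            d[parent[i]] += gax_eff[i]
            if theta != 1.0:
                iax = (1.0 - theta) * gax[i] * (V[i] - V[parent[i]])
                rhs[i] -= iax
                rhs[parent[i]] += iax
        # Hines elimination (leaves to root), then back-substitution
        for i in range(n - 1, 0, -1):
            f = gax_eff[i] / d[i]
            d[parent[i]] -= f * gax_eff[i]
            rhs[parent[i]] += f * rhs[i]
        V[0] = rhs[0] / d[0]
        for i in range(1, n):
            V[i] = (rhs[i] + gax_eff[i] * V[parent[i]]) / d[i]

        vrec[k] = V[rec_idx]
        if mode == MODE_VOLTAGE:
            irec[k] = gclamp * (stim[k] - V[stim_idx])
        else:
            irec[k] = stim[k]
        for ch in range(n_ch):
            mrec[ch, k] = m[ch, gate_idx]
            hrec[ch, k] = h[ch, gate_idx]

    return vrec, irec, mrec, hrec
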