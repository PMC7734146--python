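"""Numba RK4 integration kernel for the coupled AEIF network.

The kernel advances all neurons by a block of fixed steps.  Delayed
presynaptic traces live in a ring buffer sampled on the dt grid; within
the four RK4 substages the delayed trace is held at its value for the
step's start time (an O(dt) approximation, negligible for
dt = 0.01 ms << tau_s), while the driving-force factor (V_REV - V) uses
the substage voltage estimate.  After the full step, threshold
crossings are detected and reset simultaneously; spike times are
recorded as the step-end time and the post-reset trace is written into
the history buffer, so increments become visible to targets exactly one
delay later.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_SPIKE_OVERFLOW = 1
STATUS_NONFINITE = 2

_EXP_MAX = 50.0
_BOUND = 1e100  # far beyond any physical V (mV), w (pA) or trace value
_CHECK_EVERY = 100  # state-validity sweep cadence (steps)


# fastmath flags exclude 'nnan'/'ninf' (the non-finite abort path must see
# NaNs) and 'afn' (no approximate exp: unit oracles check 1e-10 agreement)
@njit(cache=True, fastmath={"nsz", "arcp", "contract", "reassoc"})
def rk4_block(
    V, w, s, hist, n_start, n_steps,
    a, b,
    Cm, gL, EL, DT, VT, tau_w, tau_s, Vr, Ic, Vth,
    Vrev_e, Vrev_i,
    eptr, eidx, ewt, iptr, iidx, iwt,
    de, di, dt, rec_every,
    spk_n, spk_t, rec_t, rec_I,
):  # pragma: no cover - exercised via simulate.py wrappers
    N = V.shape[0]
    depth = hist.shape[0]
    ze = np.zeros(N)
    zi = np.zeros(N)
    nspk = 0
    nrec = 0
    for step in range(n_steps):
        n = n_start + step
        # delayed, weighted presynaptic trace sums per target
        ke = n - de
        if ke >= 0:
            row = ke % depth
            for j in range(N):
                acc = 0.0
                for p in range(eptr[j], eptr[j + 1]):
                    acc += ewt[p] * hist[row, eidx[p]]
                ze[j] = acc
        else:
            for j in range(N):
                ze[j] = 0.0
        ki = n - di
        if ki >= 0:
            row = ki % depth
            for j in range(N):
                acc = 0.0
                for p in range(iptr[j], iptr[j + 1]):
                    acc += iwt[p] * hist[row, iidx[p]]
                zi[j] = acc
        else:
            for j in range(N):
                zi[j] = 0.0

        # mean synaptic current at the step-start time
        if rec_every > 0 and n % rec_every == 0:
            tot = 0.0
            for j in range(N):
                tot += (Vrev_e - V[j]) * ze[j] + (Vrev_i - V[j]) * zi[j]
            rec_t[nrec] = n * dt
            rec_I[nrec] = tot / N
            nrec += 1

        # one RK4 step per neuron (delayed traces frozen at time n*dt)
        for j in range(N):
            vj = V[j]
            wj = w[j]
            sj = s[j]
            aj = a[j]
            zej = ze[j]
            zij = zi[j]

            arg = (vj - VT) / DT
            if arg > _EXP_MAX:
                arg = _EXP_MAX
            dV1 = (-gL * (vj - EL) + gL * DT * np.exp(arg) - wj + Ic
                   + (Vrev_e - vj) * zej + (Vrev_i - vj) * zij) / Cm
            dw1 = (aj * (vj - EL) - wj) / tau_w
            ds1 = -sj / tau_s

            v2 = vj + 0.5 * dt * dV1
            w2 = wj + 0.5 * dt * dw1
            s2 = sj + 0.5 * dt * ds1
            arg = (v2 - VT) / DT
            if arg > _EXP_MAX:
                arg = _EXP_MAX
            dV2 = (-gL * (v2 - EL) + gL * DT * np.exp(arg) - w2 + Ic
                   + (Vrev_e - v2) * zej + (Vrev_i - v2) * zij) / Cm
            dw2 = (aj * (v2 - EL) - w2) / tau_w
            ds2 = -s2 / tau_s

            v3 = vj + 0.5 * dt * dV2
            w3 = wj + 0.5 * dt * dw2
            s3 = sj + 0.5 * dt * ds2
            arg = (v3 - VT) / DT
            if arg > _EXP_MAX:
                arg = _EXP_MAX
            dV3 = (-gL * (v3 - EL) + gL * DT * np.exp(arg) - w3 + Ic
                   + (Vrev_e - v3) * zej + (Vrev_i - v3) * zij) / Cm
            dw3 = (aj * (v3 - EL) - w3) / tau_w
            ds3 = -s3 / tau_s

            v4 = vj + dt * dV3
            w4 = wj + dt * dw3
            s4 = sj + dt * ds3
            arg = (v4 - VT) / DT
            if arg > _EXP_MAX:
                arg = _EXP_MAX
            dV4 = (-gL * (v4 - EL) + gL * DT * np.exp(arg) - w4 + Ic
                   + (Vrev_e - v4) * zej + (Vrev_i - v4) * zij) / Cm
            dw4 = (aj * (v4 - EL) - w4) / tau_w
            ds4 = -s4 / tau_s

            vn = vj + dt * (dV1 + 2.0 * dV2 + 2.0 * dV3 + dV4) / 6.0
            wn = wj + dt * (dw1 + 2.0 * dw2 + 2.0 * dw3 + dw4) / 6.0
            sn = sj + dt * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4) / 6.0

            V[j] = vn
            w[j] = wn
            s[j] = sn

        # simultaneous threshold detection / reset; advance history
        row2 = (n + 1) % depth
        for j in range(N):
            if V[j] > Vth:
                if nspk >= spk_n.shape[0]:
                    return nspk, nrec, STATUS_SPIKE_OVERFLOW, j, n + 1
                V[j] = Vr
                w[j] += b[j]
                s[j] += 1.0
                spk_n[nspk] = j
                spk_t[nspk] = (n + 1) * dt
                nspk += 1
            hist[row2, j] = s[j]

        # periodic state-validity sweep.  A NaN/inf state persists (NaN
        # never crosses the threshold, so it is never reset away), so a
        # sweep every _CHECK_EVERY steps misses nothing; the reported
        # time is the detection time, within _CHECK_EVERY * dt of onset.
        # The range test rather than isfinite rejects NaN (comparisons
        # are false) and +/-inf even under the fastmath flags above.
        if (step + 1) % _CHECK_EVERY == 0 or step == n_steps - 1:
            for j in range(N):
                vj = V[j]
                wj = w[j]
                sj = s[j]
                ok = ((-_BOUND <= vj) and (vj <= _BOUND)
                      and (-_BOUND <= wj) and (wj <= _BOUND)
                      and (-_BOUND <= sj) and (sj <= _BOUND))
                if not ok:
                    return nspk, nrec, STATUS_NONFINITE, j, n + 1

    # final sample of the mean current at the block-end time
    n = n_start + n_steps
    if rec_every > 0 and n % rec_every == 0:
        ke = n - de
        if ke >= 0:
            row = ke % depth
            for j in range(N):
                acc = 0.0
                for p in range(eptr[j], eptr[j + 1]):
                    acc += ewt[p] * hist[row, eidx[p]]
                ze[j] = acc
        else:
            for j in range(N):
                ze[j] = 0.0
        ki = n - di
        if ki >= 0:
            row = ki % depth
            for j in range(N):
                acc = 0.0
                for p in range(iptr[j], iptr[j + 1]):
                    acc += iwt[p] * hist[row, iidx[p]]
                zi[j] = acc
        else:
            for j in range(N):
                zi[j] = 0.0
        tot = 0.0
        for j in range(N):
            tot += (Vrev_e - V[j]) * ze[j] + (Vrev_i - V[j]) * zi[j]
        rec_t[nrec] = n * dt
        rec_I[nrec] = tot / N
        nrec += 1

    return nspk, nrec, STATUS_OK, -1, -1
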