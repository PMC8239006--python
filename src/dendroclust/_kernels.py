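"""Numba inner loops for the time-stepped plasticity models.

Explicit-Euler updates with all right-hand sides evaluated at the step
start; the pure-python steppers in :mod:`dendroclust.plasticity` are the
reference these kernels are tested against.  State arrays are updated in
place; scalar bookkeeping travels in small int64/float64 arrays so the
kernels stay resumable across chunks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# bap_state layout (int64): [uniform_ptr, refractory_until_step,
#                            bap_active_until_step, global_step_offset,
#                            prev_above_threshold, bap_count]
BAP_UPTR, BAP_REFR, BAP_UNTIL, BAP_OFFSET, BAP_PREV, BAP_COUNT = range(6)


@njit(cache=True)
def _sigmoid_mix(I, gamma, c1, c2, c3):
    if gamma == 0.0:
        return I
    return gamma * c1 / (1.0 + np.exp(-c2 * (I - c3))) + (1.0 - gamma) * I


@njit(cache=True)
def generalized_chunk(x, s, w, v, u, u_bap, dt,
                      tau_v, tau_u, tau_w, phi, rho,
                      freeze_w, dw_sum,
                      gamma, c1, c2, c3,
                      coop_on, coop_nbr, coop_timing_steps, coop_min_count,
                      coop_include_self, last_active,
                      bap_on, s_soma, A_th, B_amp, bap_prob,
                      bap_uniforms, bap_state, bap_per_step,
                      refr_steps, bap_dur_steps, bap_burst_events,
                      rec_stride, w_rec, a_rec):
    """Advance the generalized model over one chunk.

    x: (N, T) uint8 event indicators on the dt grid.  dw_sum accumulates
    u*(v+rho) (gated) per synapse whether or not w is frozen.  Records
    (w_rec (R, N), a_rec (R,)) are filled every rec_stride steps when
    rec_stride > 0.
    """
    N, T = x.shape
    av = dt / tau_v
    au = dt / tau_u
    aw = dt / tau_w
    rec_i = 0
    for t in range(T):
        gstep = bap_state[BAP_OFFSET] + t
        # somatic accumulator from the state at step start
        # bAP-fed component of u is excluded (no feedback loop)
        A = 0.0
        if bap_on or rec_stride > 0:
            for k in range(N):
                A += w[k] * (u[k] - u_bap[k])
        if bap_on:
            above = A >= A_th
            crossing = above and (bap_per_step or bap_state[BAP_PREV] == 0)
            if crossing and gstep >= bap_state[BAP_REFR]:
                ui = bap_uniforms[bap_state[BAP_UPTR] % bap_uniforms.shape[0]]
                bap_state[BAP_UPTR] += 1
                bap_state[BAP_REFR] = gstep + refr_steps
                if ui < bap_prob:
                    burst_steps = bap_dur_steps * (2 * bap_burst_events - 1)
                    bap_state[BAP_UNTIL] = gstep + burst_steps
                    bap_state[BAP_REFR] = gstep + burst_steps + refr_steps
                    bap_state[BAP_COUNT] += 1
            bap_state[BAP_PREV] = 1 if above else 0
        B_t = 0.0
        if bap_on and gstep < bap_state[BAP_UNTIL]:
            # burst: bap_burst_events pulses of one event duration at
            # 2*x_dur onset spacing (the somatic burst convention)
            burst_steps = bap_dur_steps * (2 * bap_burst_events - 1)
            phase = gstep - (bap_state[BAP_UNTIL] - burst_steps)
            if (phase // bap_dur_steps) % 2 == 0:
                B_t = 1.0

        if rec_stride > 0 and t % rec_stride == 0:
            for k in range(N):
                w_rec[rec_i, k] = w[k]
            a_rec[rec_i] = A
            rec_i += 1

        # synaptic drive from active synapses (state at step start)
        du = np.zeros(N)
        for l in range(N):
            if x[l, t] != 0:
                wl = w[l]
                for k in range(N):
                    du[k] += s[k, l] * wl
                if coop_on:
                    last_active[l] = gstep
        dw_step = np.empty(N)
        for k in range(N):
            I = _sigmoid_mix(du[k], gamma, c1, c2, c3)
            if bap_on:
                I += s_soma[k] * B_amp * B_t
            gate = 1.0
            if coop_on:
                cnt = 0
                for l in range(N):
                    if coop_nbr[k, l] != 0:
                        if l == k and not coop_include_self:
                            continue
                        if gstep - last_active[l] <= coop_timing_steps:
                            cnt += 1
                if cnt <= coop_min_count:
                    gate = 0.0
            dw_step[k] = gate * u[k] * (v[k] + rho)
            # accumulator updates (old values already consumed)
            v[k] += av * (-v[k] + phi * x[k, t])
            u[k] += au * (-u[k] + I)
            if bap_on:
                u_bap[k] += au * (-u_bap[k] + s_soma[k] * B_amp * B_t)
        for k in range(N):
            dw_sum[k] += dw_step[k]
            if not freeze_w:
                wk = w[k] + aw * dw_step[k]
                if wk < 0.0:
                    wk = 0.0
                elif wk > 1.0:
                    wk = 1.0
                w[k] = wk
    bap_state[BAP_OFFSET] += T
    return rec_i


@njit(cache=True)
def neurotrophin_chunk(x, s, W, M, Y, Y_bap, P, B, dt,
                       tau_M, tau_Y, tau_P, tau_B, tau_W,
                       phi, eta, alpha, beta,
                       freeze_w, dw_sum,
                       ext_drive, ext_gain,
                       gaba_sign, x_gaba, W_gaba, s_eg, y_floor,
                       bap_on, s_soma, A_th, B_amp, bap_prob,
                       bap_uniforms, bap_state, bap_per_step,
                       refr_steps, bap_dur_steps, bap_burst_events,
                       rec_stride, w_rec):
    """Advance the full neurotrophin model over one chunk.

    ext_drive (T,) with per-synapse gain ext_gain feeds an additive
    calcium term (the paired-burst protocol's postsynaptic pulse,
    amplitude included in ext_drive).  gaba_sign is +1 (depolarizing),
    -1 (hyperpolarizing) or 0 (no GABA); scenario A's positivity
    constraint on calcium is applied when y_floor is set.  GABA
    efficacies follow the proximity-weighted B-P of the excitatory
    population and are clipped to [0, 1].
    """
    N, T = x.shape
    NG = W_gaba.shape[0]
    aM = dt / tau_M
    aY = dt / tau_Y
    aP = dt / tau_P
    aB = dt / tau_B
    aW = dt / tau_W
    rec_i = 0
    for t in range(T):
        gstep = bap_state[BAP_OFFSET] + t
        A = 0.0
        if bap_on:
            for k in range(N):
                A += W[k] * (Y[k] - Y_bap[k])
            above = A >= A_th
            crossing = above and (bap_per_step or bap_state[BAP_PREV] == 0)
            if crossing and gstep >= bap_state[BAP_REFR]:
                ui = bap_uniforms[bap_state[BAP_UPTR] % bap_uniforms.shape[0]]
                bap_state[BAP_UPTR] += 1
                bap_state[BAP_REFR] = gstep + refr_steps
                if ui < bap_prob:
                    burst_steps = bap_dur_steps * (2 * bap_burst_events - 1)
                    bap_state[BAP_UNTIL] = gstep + burst_steps
                    bap_state[BAP_REFR] = gstep + burst_steps + refr_steps
                    bap_state[BAP_COUNT] += 1
            bap_state[BAP_PREV] = 1 if above else 0
        B_t = 0.0
        if bap_on and gstep < bap_state[BAP_UNTIL]:
            burst_steps = bap_dur_steps * (2 * bap_burst_events - 1)
            phase = gstep - (bap_state[BAP_UNTIL] - burst_steps)
            if (phase // bap_dur_steps) % 2 == 0:
                B_t = 1.0

        if rec_stride > 0 and t % rec_stride == 0:
            for k in range(N):
                w_rec[rec_i, k] = W[k]
            rec_i += 1

        dY = np.zeros(N)
        for l in range(N):
            if x[l, t] != 0:
                Wl = W[l]
                for k in range(N):
                    dY[k] += s[k, l] * Wl
        if NG > 0 and gaba_sign != 0:
            for g in range(NG):
                if x_gaba[g, t] != 0:
                    Wg = W_gaba[g]
                    for k in range(N):
                        dY[k] += gaba_sign * s_eg[k, g] * Wg
        # GABA plasticity from current B, P
        if NG > 0:
            for g in range(NG):
                acc = 0.0
                for l in range(N):
                    acc += s_eg[l, g] * (B[l] - P[l])
                wg = W_gaba[g] + aW * acc
                if wg < 0.0:
                    wg = 0.0
                elif wg > 1.0:
                    wg = 1.0
                W_gaba[g] = wg
        for k in range(N):
            Yk = Y[k]
            Mk = M[k]
            Pk = P[k]
            Bk = B[k]
            dw = alpha * Bk - beta * Pk
            dw_sum[k] += dw
            if not freeze_w:
                Wk = W[k] + aW * dw
                if Wk < 0.0:
                    Wk = 0.0
                elif Wk > 1.0:
                    Wk = 1.0
                W[k] = Wk
            drive = dY[k]
            if bap_on:
                drive += s_soma[k] * B_amp * B_t
            drive += ext_gain[k] * ext_drive[t]
            M[k] = Mk + aM * (-Mk + phi * x[k, t])
            if bap_on:
                Y_bap[k] += aY * (-Y_bap[k] + s_soma[k] * B_amp * B_t)
            Ynew = Yk + aY * (-Yk + drive)
            if y_floor and Ynew < 0.0:
                Ynew = 0.0
            Y[k] = Ynew
            conv = Mk * Pk
            P[k] = Pk + aP * (-Pk + (1.0 - eta) * Yk - conv)
            B[k] = Bk + aB * (-Bk + eta * Yk + conv)
    bap_state[BAP_OFFSET] += T
    return rec_i


@njit(cache=True)
def blob_drive(out, wave_t0, wave_psi, wave_p0,
               blob_start, blob_end, blob_q, blob_jn, blob_amp,
               lc, Mi, ampl,
               speed, life, loop_ms, t0_ms, t1_ms, bin_ms, peak_cut):
    """Accumulate closed-form blob-shower drives into out (N, n_bins).

    Per (lobe, blob) pair the response along the sweep coordinate p is
    a * exp(-(a0 - 2 a1 p + a2 p^2)/2); pairs whose peak falls below
    peak_cut are skipped and the remaining ones are evaluated only on the
    bins where they exceed the cut.
    """
    n_bins = out.shape[1]
    N = lc.shape[0]
    W = wave_t0.shape[0]
    k0 = int(np.floor((t0_ms - life) / loop_ms))
    k1 = int(np.floor(t1_ms / loop_ms))
    for rep in range(k0, k1 + 1):
        for j in range(W):
            onset = wave_t0[j] + rep * loop_ms
            if onset > t1_ms or onset + life < t0_ms:
                continue
            nx = np.cos(wave_psi[j])
            ny = np.sin(wave_psi[j])
            tx = -ny
            ty = nx
            for b in range(blob_start[j], blob_end[j]):
                q = blob_q[b]
                jn = blob_jn[b]
                ab = blob_amp[b]
                for k in range(N):
                    for l in range(2):
                        a = ampl[k, l] * ab
                        if a == 0.0:
                            continue
                        rx = lc[k, l, 0] - q * tx - jn * nx
                        ry = lc[k, l, 1] - q * ty - jn * ny
                        m11 = Mi[k, l, 0]
                        m12 = Mi[k, l, 1]
                        m22 = Mi[k, l, 2]
                        Mr1 = m11 * rx + m12 * ry
                        Mr2 = m12 * rx + m22 * ry
                        a0 = rx * Mr1 + ry * Mr2
                        a1 = nx * Mr1 + ny * Mr2
                        a2 = nx * nx * m11 + 2.0 * nx * ny * m12 + ny * ny * m22
                        lim = np.log(peak_cut / abs(a))
                        disc = a1 * a1 - a2 * (a0 + 2.0 * lim)
                        if disc <= 0.0:
                            continue
                        rootd = np.sqrt(disc)
                        plo = (a1 - rootd) / a2
                        phi_ = (a1 + rootd) / a2
                        tlo = onset + (plo - wave_p0[j]) * 1e3 / speed
                        thi = onset + (phi_ - wave_p0[j]) * 1e3 / speed
                        ilo = int(np.floor((tlo - t0_ms) / bin_ms))
                        ihi = int(np.ceil((thi - t0_ms) / bin_ms))
                        if ilo < 0:
                            ilo = 0
                        if ihi > n_bins:
                            ihi = n_bins
                        for i in range(ilo, ihi):
                            tt = t0_ms + (i + 0.5) * bin_ms
                            if tt < onset or tt > onset + life:
                                continue
                            p = wave_p0[j] + speed * (tt - onset) / 1e3
                            out[k, i] += a * np.exp(
                                -0.5 * (a0 - 2.0 * a1 * p + a2 * p * p))
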