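"""Compiled inner loop of the simulator.

The integrator advances all neurons with a fixed step dt. Receptor drives
are held as per-postsynaptic-neuron aggregates ``sum_j w_ij s_j``: for
first-order kinetics (AMPA, GABA, external AMPA) the aggregate obeys the
same exponential decay as the individual gating variables, so it is exact
— decay the aggregate each step and scatter presynaptic weights into it
on spikes. The NMDA aggregate additionally receives the saturation source
``alpha*x_j*(1-s_j)*dt`` scattered over the outgoing synapses of every
presynaptic cell whose rise variable x is above a small cutoff (x decays
with a 2 ms time constant, so the cutoff truncates a tail of relative
size ~x_eps).

Update order within one step (mirrored by the NumPy reference path):

1. synaptic currents from the state at t; exponential-Euler membrane
   update; threshold test, reset, refractory arming (spikes stamped t+dt)
2. plasticity: decay traces, apply weight updates for this step's spikes
   using trace values that exclude those spikes (simultaneous pre/post
   pairs contribute nothing), clip, write through to receptor weights,
   then increment traces
3. gating: decay aggregates and gating variables, add the NMDA source,
   scatter spike increments, add background events

Spikes from a silenced (clamped) neuron never occur; its gating decays
naturally. All randomness comes from numba's global legacy RNG, seeded
once per run through :func:`seed_rng`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_NONFINITE = 2


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def run_chunk(
    # time
    t0, dt, n_steps,
    # membrane (per neuron)
    v, v_rest, v_th, g_l, m_decay, tau_ref, refr_until, clamped, is_exc,
    # receptor constants
    g_ampa, g_nmda, g_gaba, mg, v_e, w_ext,
    d_ampa, d_gaba, d_nmda, d_x, alpha, x_eps, gaba_pre_mode,
    # gating state
    s_ext, agg_ampa, agg_gaba, agg_gaba_v, s_nmda, x_nmda, agg_nmda,
    # connectivity, CSR by presynaptic neuron
    ampa_indptr, ampa_post, ampa_w,
    nmda_indptr, nmda_post, nmda_w,
    gaba_indptr, gaba_post, gaba_w, gaba_wv, gaba_pre_vrest,
    # inputs
    i_ext, p_bg, bg_events, use_bg_events,
    # excitatory plasticity
    plas_on, a_plus, a_minus, d_tr_plus, d_tr_minus, w_lo, w_hi,
    pre_tr, post_tr,
    pl_out_indptr, pl_out_syn, pl_in_indptr, pl_in_syn,
    pl_pre, pl_post, pl_w, pl_ampa_idx, pl_nmda_idx,
    # inhibitory plasticity (PV->E GABA)
    iplas_on, b_plus, b_minus, d_trf, d_trs, iw_lo, iw_hi,
    tr_fast, tr_slow,
    ipl_out_indptr, ipl_out_syn, ipl_in_indptr, ipl_in_syn,
    ipl_pre, ipl_post, ipl_w, ipl_gaba_idx,
    # outputs
    spike_t, spike_id,
    rec_ids, rec_every, rec_phase, rec_v,
    out_info,
):
    n = v.shape[0]
    n_exc = 0
    for i in range(n):
        if is_exc[i]:
            n_exc += 1
    spiked = np.empty(n, np.int32)
    n_spikes = 0
    cap = spike_t.shape[0]
    rec_n = rec_ids.shape[0]
    rec_row = 0

    for k in range(n_steps):
        t = t0 + k * dt
        t_next = t + dt
        nsp = 0

        # -- membrane update and spike detection --------------------------
        for i in range(n):
            if clamped[i]:
                v[i] = v_rest[i]
                continue
            if t < refr_until[i]:
                v[i] = v_rest[i]
                continue
            vi = v[i]
            isyn = i_ext[i]
            isyn -= g_ampa * (vi - v_e) * (w_ext * s_ext[i] + agg_ampa[i])
            b = 1.0 / (1.0 + mg * math.exp(-0.062 * vi) / 3.57)
            isyn -= g_nmda * (vi - v_e) * b * agg_nmda[i]
            if gaba_pre_mode:
                isyn -= g_gaba * (vi * agg_gaba[i] - agg_gaba_v[i])
            else:
                isyn -= g_gaba * (vi - v_rest[i]) * agg_gaba[i]
            vinf = v_rest[i] + isyn / g_l[i]
            vnew = vinf + (vi - vinf) * m_decay[i]
            if not math.isfinite(vnew):
                out_info[0] = n_spikes
                out_info[1] = STATUS_NONFINITE
                out_info[2] = i
                out_info[3] = k
                return
            if vnew >= v_th[i]:
                spiked[nsp] = i
                nsp += 1
                v[i] = v_rest[i]
                refr_until[i] = t_next + tau_ref[i]
                if n_spikes >= cap:
                    out_info[0] = n_spikes
                    out_info[1] = STATUS_OVERFLOW
                    out_info[2] = i
                    out_info[3] = k
                    return
                spike_t[n_spikes] = t_next
                spike_id[n_spikes] = i
                n_spikes += 1
            else:
                v[i] = vnew

        # -- plasticity ----------------------------------------------------
        if plas_on:
            for i in range(n):
                pre_tr[i] *= d_tr_plus
                post_tr[i] *= d_tr_minus
            for q in range(nsp):
                z = spiked[q]
                # z as presynaptic: depression by earlier post spikes
                for a in range(pl_out_indptr[z], pl_out_indptr[z + 1]):
                    s = pl_out_syn[a]
                    wv = pl_w[s] - a_minus * post_tr[pl_post[s]]
                    if wv < w_lo:
                        wv = w_lo
                    elif wv > w_hi:
                        wv = w_hi
                    pl_w[s] = wv
                    if pl_ampa_idx[s] >= 0:
                        ampa_w[pl_ampa_idx[s]] = wv
                    if pl_nmda_idx[s] >= 0:
                        nmda_w[pl_nmda_idx[s]] = wv
                # z as postsynaptic: potentiation by earlier pre spikes
                for a in range(pl_in_indptr[z], pl_in_indptr[z + 1]):
                    s = pl_in_syn[a]
                    wv = pl_w[s] + a_plus * pre_tr[pl_pre[s]]
                    if wv < w_lo:
                        wv = w_lo
                    elif wv > w_hi:
                        wv = w_hi
                    pl_w[s] = wv
                    if pl_ampa_idx[s] >= 0:
                        ampa_w[pl_ampa_idx[s]] = wv
                    if pl_nmda_idx[s] >= 0:
                        nmda_w[pl_nmda_idx[s]] = wv
            for q in range(nsp):
                z = spiked[q]
                pre_tr[z] += 1.0
                post_tr[z] += 1.0

        if iplas_on:
            for i in range(n):
                tr_fast[i] *= d_trf
                tr_slow[i] *= d_trs
            for q in range(nsp):
                z = spiked[q]
                for a in range(ipl_out_indptr[z], ipl_out_indptr[z + 1]):
                    s = ipl_out_syn[a]
                    i2 = ipl_post[s]
                    wv = ipl_w[s] + b_plus * tr_fast[i2] - b_minus * tr_slow[i2]
                    if wv < iw_lo:
                        wv = iw_lo
                    elif wv > iw_hi:
                        wv = iw_hi
                    ipl_w[s] = wv
                    gi = ipl_gaba_idx[s]
                    gaba_w[gi] = wv
                    gaba_wv[gi] = wv * gaba_pre_vrest[gi]
                for a in range(ipl_in_indptr[z], ipl_in_indptr[z + 1]):
                    s = ipl_in_syn[a]
                    j2 = ipl_pre[s]
                    wv = ipl_w[s] + b_plus * tr_fast[j2] - b_minus * tr_slow[j2]
                    if wv < iw_lo:
                        wv = iw_lo
                    elif wv > iw_hi:
                        wv = iw_hi
                    ipl_w[s] = wv
                    gi = ipl_gaba_idx[s]
                    gaba_w[gi] = wv
                    gaba_wv[gi] = wv * gaba_pre_vrest[gi]
            for q in range(nsp):
                z = spiked[q]
                tr_fast[z] += 1.0
                tr_slow[z] += 1.0

        # -- gating --------------------------------------------------------
        for i in range(n):
            s_ext[i] *= d_ampa
            agg_ampa[i] *= d_ampa
            agg_gaba[i] *= d_gaba
            agg_gaba_v[i] *= d_gaba
            agg_nmda[i] *= d_nmda
        for j in range(n):
            if not is_exc[j]:
                continue
            xj = x_nmda[j]
            if xj > x_eps:
                src = alpha * xj * (1.0 - s_nmda[j]) * dt
                s_nmda[j] = s_nmda[j] * d_nmda + src
                for a in range(nmda_indptr[j], nmda_indptr[j + 1]):
                    agg_nmda[nmda_post[a]] += nmda_w[a] * src
            else:
                s_nmda[j] *= d_nmda
            x_nmda[j] *= d_x
        for q in range(nsp):
            z = spiked[q]
            if is_exc[z]:
                for a in range(ampa_indptr[z], ampa_indptr[z + 1]):
                    agg_ampa[ampa_post[a]] += ampa_w[a]
                x_nmda[z] += 1.0
            else:
                for a in range(gaba_indptr[z], gaba_indptr[z + 1]):
                    agg_gaba[gaba_post[a]] += gaba_w[a]
                    agg_gaba_v[gaba_post[a]] += gaba_wv[a]
        if use_bg_events:
            for i in range(n):
                s_ext[i] += bg_events[k, i]
        else:
            r = np.random.random(n)
            for i in range(n):
                if r[i] < p_bg[i]:
                    s_ext[i] += 1.0

        # -- membrane recording -------------------------------------------
        if rec_n > 0 and (k + rec_phase + 1) % rec_every == 0:
            for q in range(rec_n):
                rec_v[rec_row, q] = v[rec_ids[q]]
            rec_row += 1

    out_info[0] = n_spikes
    out_info[1] = STATUS_OK
    out_info[2] = -1
    out_info[3] = rec_row
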