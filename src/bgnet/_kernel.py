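"""Numba-compiled integration core.

One call advances the whole network for ``n_steps`` of size ``dt``:

* membrane equations (LIF, or AdEx with exponential spike initiation and an
  adaptation current) integrated with the midpoint (RK2) method;
* per-channel alpha-shaped conductances advanced with their exact
  exponential propagator (the two linear synaptic state variables have a
  closed-form update, so only the membrane is integrated approximately);
* conduction delays realized as a circular buffer of pending conductance
  increments, one slot per time step;
* background and stimulus drive injected as Poisson event counts.

Poisson inputs are generated per *group* (the neurons of one population
sharing a rate and weight): one Poisson draw for the group's total event
count per step, scattered uniformly over members. By Poisson thinning this
is exactly equivalent to independent per-neuron Poisson processes and far
cheaper than one generator call per neuron per step.

The kernel is deterministic given its seed and single-threaded; all
randomness flows through one ``np.random`` stream seeded at entry. Stimulus
draws happen only while the stimulus rate is nonzero, so a run with a
stimulus reproduces the no-stimulus trajectory exactly up to stimulus onset
when given the same seed (used by the phase-locked protocol). Spike
delivery targets lie at least one full delay step in the future, so the
single fused pass over neurons has no within-step ordering hazard.
"""

from __future__ import annotations

import numpy as np
from numba import njit

E = np.e


@njit(cache=True, fastmath=True)
def run_kernel(
    n_steps, dt, seed,
    # per-neuron parameters
    C_m, g_L, E_L, V_th, V_reset, E_ex, E_in, tau_ex, tau_in, I_e,
    is_adex, a_ad, b_ad, delta_T, tau_w, V_peak, ref_steps,
    # connectivity (out-edge CSR over global neuron ids)
    out_ptr, out_tgt, out_w, out_dsteps,
    n_buf,
    # input groups: contiguous member slices [g_ptr[k], g_ptr[k+1]) into
    # g_members; per-group per-neuron lam (events/step), weight, and flags
    g_ptr, g_members, g_lam, g_w, g_is_stim, g_stim_lam_scale,
    # per-step stimulus rate (events/step/neuron) and background scale
    stim_lam, bg_scale,
    # initial state
    V0, w0,
    # outputs
    spike_ids, spike_steps,
    # optional membrane trace (record_id < 0 disables)
    record_id, v_trace,
    # membrane substeps for the AdEx populations (their synaptic
    # conductances can be hundreds of nS, making the membrane stiff)
    n_sub=2,
):
    np.random.seed(seed)
    n = C_m.shape[0]
    n_groups = g_ptr.shape[0] - 1

    V = V0.copy()
    w_ad = w0.copy()
    g_ex = np.zeros(n)
    h_ex = np.zeros(n)
    g_in = np.zeros(n)
    h_in = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)

    dec_ex = np.exp(-dt / tau_ex)
    dec_in = np.exp(-dt / tau_in)
    # conversion from summed arriving peak conductance |J| to the h state
    # variable such that one arrival peaks at exactly |J| after tau_syn
    amp_ex = E / tau_ex
    amp_in = E / tau_in
    inv_C = 1.0 / C_m
    inv_tw = 1.0 / tau_w
    inv_dT = 1.0 / delta_T

    ring_ex = np.zeros((n_buf, n))
    ring_in = np.zeros((n_buf, n))

    n_rec = 0
    cap = spike_ids.shape[0]
    overflow = False
    diverged = False
    half_dt = 0.5 * dt

    for step in range(n_steps):
        slot = step % n_buf
        lam_s = stim_lam[step]
        scale = bg_scale[step]

        # external Poisson events, one total draw per group
        for k in range(n_groups):
            lo = g_ptr[k]
            hi = g_ptr[k + 1]
            m = hi - lo
            if m == 0:
                continue
            lam = g_lam[k]
            if lam > 0.0:
                if g_is_stim[k] and scale != 1.0:
                    lam *= scale
                tot = np.random.poisson(lam * m)
                wgt = g_w[k]
                for _ in range(tot):
                    idx = g_members[lo + np.random.randint(0, m)]
                    h_ex[idx] += wgt * amp_ex[idx]
            if lam_s > 0.0 and g_stim_lam_scale[k] != 0.0:
                tot_s = np.random.poisson(lam_s * m)
                wgt_s = g_stim_lam_scale[k]
                for _ in range(tot_s):
                    idx = g_members[lo + np.random.randint(0, m)]
                    h_ex[idx] += wgt_s * amp_ex[idx]

        for i in range(n):
            # synaptic states: exact propagator of the alpha kernel pair
            he = h_ex[i]
            hi_ = h_in[i]
            ge = dec_ex[i] * (g_ex[i] + dt * he)
            gi = dec_in[i] * (g_in[i] + dt * hi_)
            he *= dec_ex[i]
            hi_ *= dec_in[i]
            arr_e = ring_ex[slot, i]
            if arr_e != 0.0:
                he += arr_e * amp_ex[i]
                ring_ex[slot, i] = 0.0
            arr_i = ring_in[slot, i]
            if arr_i != 0.0:
                hi_ += arr_i * amp_in[i]
                ring_in[slot, i] = 0.0
            g_ex[i] = ge
            h_ex[i] = he
            g_in[i] = gi
            h_in[i] = hi_

            # membrane update (midpoint RK2) or refractory clamp
            if refrac[i] > 0:
                refrac[i] -= 1
                V[i] = V_reset[i]
                if is_adex[i]:
                    # adaptation keeps evolving during refractoriness
                    dw = (a_ad[i] * (V[i] - E_L[i]) - w_ad[i]) * inv_tw[i]
                    w_ad[i] += dt * dw
                continue

            v = V[i]
            isyn0 = -ge * (v - E_ex[i]) - gi * (v - E_in[i])
            if is_adex[i]:
                # exponential-Euler substeps: the conductance and leak
                # terms are integrated with their exact propagator (the
                # total conductance can reach hundreds of nS, making the
                # membrane stiff at the global step), while the spike-
                # initiation exponential and the adaptation current are
                # held piecewise-constant within each substep
                spiked = False
                h_sub = dt / n_sub
                w_i = w_ad[i]
                for _s in range(n_sub):
                    arg = (v - V_th[i]) * inv_dT[i]
                    if arg > 16.0:
                        arg = 16.0
                    exp_term = g_L[i] * delta_T[i] * np.exp(arg)
                    g_tot = g_L[i] + ge + gi
                    i_const = (g_L[i] * E_L[i] + ge * E_ex[i]
                               + gi * E_in[i] + I_e[i] - w_i + exp_term)
                    v_inf = i_const / g_tot
                    decay = np.exp(-h_sub * g_tot * inv_C[i])
                    v_new = v_inf + (v - v_inf) * decay
                    dw = (a_ad[i] * (v - E_L[i]) - w_i) * inv_tw[i]
                    w_i += h_sub * dw
                    v = v_new
                    if v >= V_peak[i]:
                        spiked = True
                        break
                w_ad[i] = w_i
            else:
                dv1 = (-g_L[i] * (v - E_L[i]) + isyn0 + I_e[i]) * inv_C[i]
                vm = v + half_dt * dv1
                isynm = -ge * (vm - E_ex[i]) - gi * (vm - E_in[i])
                dv2 = (-g_L[i] * (vm - E_L[i]) + isynm + I_e[i]) * inv_C[i]
                v += dt * dv2
                spiked = v >= V_th[i]

            if not np.isfinite(v):
                diverged = True
                break

            if spiked:
                v = V_reset[i]
                refrac[i] = ref_steps
                if is_adex[i]:
                    w_ad[i] += b_ad[i]
                if n_rec < cap:
                    spike_ids[n_rec] = i
                    spike_steps[n_rec] = step
                    n_rec += 1
                else:
                    overflow = True
                # queue delayed conductance increments at the targets
                for e in range(out_ptr[i], out_ptr[i + 1]):
                    tgt = out_tgt[e]
                    dest = (step + out_dsteps[e]) % n_buf
                    wgt = out_w[e]
                    if wgt >= 0.0:
                        ring_ex[dest, tgt] += wgt
                    else:
                        ring_in[dest, tgt] -= wgt
            V[i] = v

        if diverged:
            break
        if record_id >= 0:
            v_trace[step] = V[record_id]

    status = 0
    if overflow:
        status = 1
    if diverged:
        status = 2
    return n_rec, status
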