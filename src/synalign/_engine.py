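"""Compiled inner loop for the recurrent-network simulation.

Implements exactly the per-step schedule of :func:`synalign.sorn.run_model3`
(state update -> STDP -> iSTDP -> joint normalization -> pruning ->
structural plasticity -> intrinsic plasticity) as a single numba kernel
over dense arrays. Semantics match the pure-numpy step functions in
:mod:`synalign.sorn` — one failure draw per synapse per step shared
between the activity update and STDP eligibility, joint row rescaling
restricted to rows touched since the last rescale when normalization is
instantaneous — but the random streams differ (the kernel uses numba's
np.random, the reference path numpy Generators), so the two engines
agree statistically, not trajectory-for-trajectory.

Weight matrices are indexed W[post, pre]; the kernel additionally keeps
the supports and failure masks *transposed* (ST[pre, post]) so that the
per-presynaptic-column scans run over contiguous memory, and it draws
failure variables only for realized synapses of active presynaptic
units — silent or absent synapses transmit nothing and take part in no
plasticity, so their draws are never observable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def sorn_kernel(
    W1,
    W2,
    S1,
    S2,
    W_EI,
    W_IE,
    T_E,
    T_I,
    x0,
    y0,
    beta,
    eta_stdp,
    eta_sn,
    eta_inhib,
    h_ip,
    eta_ip,
    p_struct,
    w_sp,
    p_fail,
    noise_var,
    n_steps,
    record_every,
    seed,
    n_pot_out,
    n_dep_out,
    net_dw_out,
    record_steps_out,
    conn_frac_out,
    mean_rate_out,
):
    np.random.seed(seed)
    n_e = W1.shape[0]
    n_i = W_IE.shape[0]
    sb = np.sqrt(beta)
    a_pot = eta_stdp * sb
    a_dep = eta_stdp / sb
    sigma = np.sqrt(noise_var)
    inv_mu = 1.0 + 1.0 / h_ip
    instant = eta_sn == 1.0
    denom = n_e * (n_e - 1)

    # transposed copies: ST[pre, post] for contiguous per-column scans
    ST1 = np.ascontiguousarray(S1.T)
    ST2 = np.ascontiguousarray(S2.T)
    mT1 = np.zeros((n_e, n_e), np.uint8)
    mT2 = np.zeros((n_e, n_e), np.uint8)

    x = x0.copy()
    y = y0.copy()
    x_new = np.zeros(n_e, np.uint8)
    y_new = np.zeros(n_i, np.uint8)
    col_drawn = np.zeros(n_e, np.uint8)
    used_cols = np.empty(2 * n_e, np.int64)
    act_old = np.empty(n_e, np.int64)
    act_new = np.empty(n_e, np.int64)
    y_act = np.empty(n_i, np.int64)
    drive = np.empty(n_e, np.float64)
    row_dirty = np.ones(n_e, np.uint8)

    support1 = 0
    support2 = 0
    for i in range(n_e):
        for j in range(n_e):
            if S1[i, j]:
                support1 += 1
            if S2[i, j]:
                support2 += 1

    rate_acc = 0.0
    steps_in_block = 0
    block = 0

    for t in range(n_steps):
        # --- active sets of the previous step ---
        k_old = 0
        for i in range(n_e):
            if x[i]:
                act_old[k_old] = i
                k_old += 1
        k_y = 0
        for j in range(n_i):
            if y[j]:
                y_act[k_y] = j
                k_y += 1

        # --- failure draws for realized synapses of active sources ---
        n_used = 0
        for a in range(k_old):
            j = act_old[a]
            for i in range(n_e):
                if ST1[j, i]:
                    mT1[j, i] = np.random.random() >= p_fail
                if ST2[j, i]:
                    mT2[j, i] = np.random.random() >= p_fail
            col_drawn[j] = 1
            used_cols[n_used] = j
            n_used += 1

        # --- state update ---
        for i in range(n_e):
            drive[i] = 0.0
        for a in range(k_old):
            j = act_old[a]
            for i in range(n_e):
                if ST1[j, i] and mT1[j, i]:
                    drive[i] += W1[i, j]
                if ST2[j, i] and mT2[j, i]:
                    drive[i] += W2[i, j]
        for a in range(k_y):
            j = y_act[a]
            for i in range(n_e):
                drive[i] -= W_EI[i, j]
        k_new = 0
        for i in range(n_e):
            arg = drive[i] - T_E[i]
            if sigma > 0.0:
                arg += sigma * np.random.normal()
            if arg > 0.0:
                x_new[i] = 1
                act_new[k_new] = i
                k_new += 1
            else:
                x_new[i] = 0
        for i in range(n_i):
            arg = -T_I[i]
            for a in range(k_new):
                arg += W_IE[i, act_new[a]]
            if sigma > 0.0:
                arg += sigma * np.random.normal()
            y_new[i] = 1 if arg > 0.0 else 0

        # --- STDP: one shared mask per synapse per step; columns only
        # active at t+1 get their draws here ---
        for a in range(k_new):
            j = act_new[a]
            if not col_drawn[j]:
                for i in range(n_e):
                    if ST1[j, i]:
                        mT1[j, i] = np.random.random() >= p_fail
                    if ST2[j, i]:
                        mT2[j, i] = np.random.random() >= p_fail
                col_drawn[j] = 1
                used_cols[n_used] = j
                n_used += 1
        n_pot = 0
        n_dep = 0
        # potentiation: post fired at t+1 (rows i), pre at t (cols j)
        for a in range(k_new):
            i = act_new[a]
            for b in range(k_old):
                j = act_old[b]
                if ST1[j, i] and mT1[j, i]:
                    W1[i, j] += a_pot
                    n_pot += 1
                if ST2[j, i] and mT2[j, i]:
                    W2[i, j] += a_pot
                    n_pot += 1
        # depression: post fired at t (rows i), pre at t+1 (cols j)
        for a in range(k_old):
            i = act_old[a]
            for b in range(k_new):
                j = act_new[b]
                if ST1[j, i] and mT1[j, i]:
                    W1[i, j] -= a_dep
                    n_dep += 1
                if ST2[j, i] and mT2[j, i]:
                    W2[i, j] -= a_dep
                    n_dep += 1
        n_pot_out[t] = n_pot
        n_dep_out[t] = n_dep
        net_dw_out[t] = a_pot * n_pot - a_dep * n_dep

        # --- iSTDP on inhibitory-to-excitatory weights, floored at 0 ---
        for a in range(k_y):
            j = y_act[a]
            for i in range(n_e):
                if x_new[i]:
                    v = W_EI[i, j] + eta_inhib * inv_mu - eta_inhib
                else:
                    v = W_EI[i, j] - eta_inhib
                W_EI[i, j] = v if v > 0.0 else 0.0

        # --- joint multiplicative normalization of W1 + W2 rows ---
        if instant:
            for a in range(k_old):
                row_dirty[act_old[a]] = 1
            for a in range(k_new):
                row_dirty[act_new[a]] = 1
            for i in range(n_e):
                if not row_dirty[i]:
                    continue
                s = 0.0
                for j in range(n_e):
                    s += W1[i, j] + W2[i, j]
                if s != 0.0:
                    f = 1.0 / s
                    for j in range(n_e):
                        W1[i, j] *= f
                        W2[i, j] *= f
                row_dirty[i] = 0
        else:
            for i in range(n_e):
                s = 0.0
                for j in range(n_e):
                    s += W1[i, j] + W2[i, j]
                if s != 0.0:
                    f = 1.0 + eta_sn * (1.0 / s - 1.0)
                    for j in range(n_e):
                        W1[i, j] *= f
                        W2[i, j] *= f

        # --- prune non-positive weights (only depressed entries can
        # cross zero: rows active at t, columns active at t+1) ---
        for a in range(k_old):
            i = act_old[a]
            for b in range(k_new):
                j = act_new[b]
                if ST1[j, i] and W1[i, j] <= 0.0:
                    ST1[j, i] = False
                    W1[i, j] = 0.0
                    support1 -= 1
                    row_dirty[i] = 1
                if ST2[j, i] and W2[i, j] <= 0.0:
                    ST2[j, i] = False
                    W2[i, j] = 0.0
                    support2 -= 1
                    row_dirty[i] = 1

        # --- structural plasticity, each matrix independently ---
        if np.random.random() < p_struct:
            if support1 < denom:
                while True:
                    i = np.random.randint(0, n_e)
                    j = np.random.randint(0, n_e)
                    if i != j and not ST1[j, i]:
                        break
                ST1[j, i] = True
                W1[i, j] = w_sp
                support1 += 1
                row_dirty[i] = 1
        if np.random.random() < p_struct:
            if support2 < denom:
                while True:
                    i = np.random.randint(0, n_e)
                    j = np.random.randint(0, n_e)
                    if i != j and not ST2[j, i]:
                        break
                ST2[j, i] = True
                W2[i, j] = w_sp
                support2 += 1
                row_dirty[i] = 1

        # --- intrinsic plasticity ---
        mean_x = 0.0
        for i in range(n_e):
            T_E[i] += eta_ip * (x_new[i] - h_ip)
            mean_x += x_new[i]
        rate_acc += mean_x / n_e
        steps_in_block += 1

        # --- reset per-step failure bookkeeping, swap state ---
        for a in range(n_used):
            col_drawn[used_cols[a]] = 0
        for i in range(n_e):
            x[i] = x_new[i]
        for j in range(n_i):
            y[j] = y_new[j]

        if (t + 1) % record_every == 0 or t == n_steps - 1:
            record_steps_out[block] = t + 1
            conn_frac_out[block] = support1 / denom
            mean_rate_out[block] = rate_acc / steps_in_block
            rate_acc = 0.0
            steps_in_block = 0
            block += 1

    # write the transposed supports back
    for i in range(n_e):
        for j in range(n_e):
            S1[i, j] = ST1[j, i]
            S2[i, j] = ST2[j, i]

    return block, x, y
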