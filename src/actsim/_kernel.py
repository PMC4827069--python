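"""Numba-jitted exact SSA kernel.

One full channel rebuild per event (trait spaces here have <= ~10 traits, so
the O(|traits|^2) rebuild is cheap and keeps the simulation exact).  Channel
selection scans a flat rate vector in canonical trait order, which fixes
floating-point tie-breaking deterministically.

Competition and therapy sums exclude the focal individual's own 1/K
contribution (the scaled measure is evaluated on the population minus the
focal cell); predator-prey and cytokine terms act across classes and are not
affected.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stop codes
STOP_T_MAX = 0
STOP_ALL_EXTINCT = 1
STOP_TUMOUR_EXTINCT = 2
STOP_MAX_EVENTS = 3

STOP_REASONS = {
    STOP_T_MAX: "t_max",
    STOP_ALL_EXTINCT: "all_extinct",
    STOP_TUMOUR_EXTINCT: "tumour_extinct",
    STOP_MAX_EVENTS: "max_events",
}


@njit(cache=True)
def ssa_run(n, t0, t_max, K,
            b, d, c, cb, tkill, kburst, snat, scyt, mu, m_cum,
            bT, dT, tprod, rburst, dW,
            grid, gi0, rec_states, rec_mut,
            stop_tumour_extinct, max_events, n_mut0, seed_if_nonneg):
    """Run the SSA in place on the count vector ``n`` from t0 until a stop rule.

    Records the pre-event state at every grid time passed; returns
    (gi, t_end, stop_code, n_events, n_mut).  ``seed_if_nonneg`` >= 0 seeds
    numba's RNG stream; pass -1 to continue the current stream (segments).
    """
    if seed_if_nonneg >= 0:
        np.random.seed(seed_if_nonneg)
    nc = b.shape[0]
    nz = bT.shape[0]
    nw = dW.shape[0]
    m = grid.shape[0]
    gi = gi0
    t = t0
    n_events = 0
    n_mut = n_mut0
    stop_code = STOP_T_MAX

    # flat channel arrays: per cancer trait (birth, death, nz therapy, nc switch),
    # then per T-cell (birth, death), then per cytokine (decay)
    n_ch = nc * (2 + nz + nc) + 2 * nz + nw
    rate = np.zeros(n_ch)
    kind = np.zeros(n_ch, dtype=np.int64)
    arg_a = np.zeros(n_ch, dtype=np.int64)
    arg_b = np.zeros(n_ch, dtype=np.int64)

    while True:
        # ---- rebuild channels -------------------------------------------------
        R = 0.0
        k = 0
        for i in range(nc):
            ni = n[i]
            if ni > 0:
                Sb = 0.0
                Sd = 0.0
                for j in range(nc):
                    nj = n[j]
                    if j == i:
                        nj -= 1
                    Sb += cb[i, j] * nj
                    Sd += c[i, j] * nj
                Sb /= K
                Sd /= K
                beff = b[i] - Sb
                if beff >= 0.0:
                    dbrc = 0.0
                else:
                    dbrc = -beff
                    beff = 0.0
                rate[k] = ni * beff
                kind[k] = 0
                arg_a[k] = i
                R += rate[k]
                k += 1
                rate[k] = ni * (d[i] + Sd + dbrc)
                kind[k] = 1
                arg_a[k] = i
                R += rate[k]
                k += 1
                for z in range(nz):
                    r = ni * tkill[i, z] * n[nc + z] / K
                    if r > 0.0:
                        rate[k] = r
                        kind[k] = 2
                        arg_a[k] = i
                        arg_b[k] = z
                        R += r
                        k += 1
                for j in range(nc):
                    if j == i:
                        continue
                    s = snat[i, j]
                    for w in range(nw):
                        s += scyt[w, i, j] * n[nc + nz + w] / K
                    if s > 0.0:
                        rate[k] = ni * s
                        kind[k] = 3
                        arg_a[k] = i
                        arg_b[k] = j
                        R += rate[k]
                        k += 1
        for z in range(nz):
            nzp = n[nc + z]
            if nzp > 0:
                prey = 0.0
                for i in range(nc):
                    prey += tprod[z, i] * n[i]
                r = nzp * (bT[z] + prey / K)
                if r > 0.0:
                    rate[k] = r
                    kind[k] = 4
                    arg_a[k] = z
                    R += r
                    k += 1
                r = nzp * dT[z]
                if r > 0.0:
                    rate[k] = r
                    kind[k] = 5
                    arg_a[k] = z
                    R += r
                    k += 1
        for w in range(nw):
            nwp = n[nc + nz + w]
            if nwp > 0:
                r = nwp * dW[w]
                if r > 0.0:
                    rate[k] = r
                    kind[k] = 6
                    arg_a[k] = w
                    R += r
                    k += 1

        if R <= 0.0:
            # absorbing state: fill the rest of the grid with the frozen state
            while gi < m:
                for q in range(n.shape[0]):
                    rec_states[gi, q] = n[q]
                rec_mut[gi] = n_mut
                gi += 1
            stop_code = STOP_ALL_EXTINCT
            break

        dt = -np.log(np.random.random()) / R
        t_next = t + dt

        # record all grid times strictly before the next event
        while gi < m and grid[gi] < t_next:
            if grid[gi] > t_max:
                break
            for q in range(n.shape[0]):
                rec_states[gi, q] = n[q]
            rec_mut[gi] = n_mut
            gi += 1

        if t_next > t_max:
            t = t_max
            stop_code = STOP_T_MAX
            break
        t = t_next
        n_events += 1

        # ---- select channel (cumulative scan in canonical order) -------------
        target = np.random.random() * R
        acc = 0.0
        sel = k - 1
        for idx in range(k):
            acc += rate[idx]
            if target < acc:
                sel = idx
                break

        kd = kind[sel]
        if kd == 0:  # cancer birth, mutation resolved here
            i = arg_a[sel]
            mutated = False
            if mu[i] > 0.0 and np.random.random() < mu[i]:
                tot = m_cum[i, nc - 1]
                if tot > 0.0:
                    rmu = np.random.random() * tot
                    j = nc - 1
                    for q in range(nc):
                        if rmu < m_cum[i, q]:
                            j = q
                            break
                    n[j] += 1
                    n_mut += 1
                    mutated = True
            if not mutated:
                n[i] += 1
        elif kd == 1:  # cancer death (natural + competition + brc excess)
            n[arg_a[sel]] -= 1
        elif kd == 2:  # therapy kill with cytokine burst
            i = arg_a[sel]
            z = arg_b[sel]
            n[i] -= 1
            for w in range(nw):
                n[nc + nz + w] += kburst[i, z, w]
        elif kd == 3:  # phenotype switch
            n[arg_a[sel]] -= 1
            n[arg_b[sel]] += 1
        elif kd == 4:  # T-cell reproduction with cytokine burst
            z = arg_a[sel]
            n[nc + z] += 1
            for w in range(nw):
                n[nc + nz + w] += rburst[z, w]
        elif kd == 5:
            n[nc + arg_a[sel]] -= 1
        else:
            n[nc + nz + arg_a[sel]] -= 1

        if stop_tumour_extinct:
            tum = 0
            for i in range(nc):
                tum += n[i]
            if tum == 0:
                stop_code = STOP_TUMOUR_EXTINCT
                break
        if n_events >= max_events:
            stop_code = STOP_MAX_EVENTS
            break

    return gi, t, stop_code, n_events, n_mut
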