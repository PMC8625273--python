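"""Numba-compiled simulation kernels.

The direct-method kernel mirrors :mod:`retrodyn.reactions` channel for
channel; any change there must be reflected here (a consistency test
compares the two).  States are (L, S, R_L, S2) int64; parameters arrive as
a flat float64 vector to keep one compiled signature for all variants.

Parameter vector layout:
    0: b_R_eff (slope of linear production; ignored when use_mm)
    1: b_L_eff   2: b_S_eff   3: d_R   4: d_L   5: d_S   6: V
    7: v_max_eff 8: k_r       9: b_S2_eff
Flags: use_mm, has_s2, literal_counts (int64 0/1).
"""

from __future__ import annotations

import numpy as np
from numba import njit


def pack_params(params) -> tuple[np.ndarray, int, int]:
    """Flatten a ModelParameters into (vector, use_mm, has_s2)."""
    from .params import effective_rate_constants

    r = effective_rate_constants(params)
    vec = np.array(
        [
            r.b_R_eff if r.b_R_eff is not None else 0.0,
            r.b_L_eff,
            r.b_S_eff,
            params.d_R,
            params.d_L,
            params.d_S,
            params.V,
            r.v_max_eff if r.v_max_eff is not None else 0.0,
            r.k_r if r.k_r is not None else 0.0,
            r.b_S2_eff if r.b_S2_eff is not None else 0.0,
        ],
        dtype=np.float64,
    )
    return vec, int(r.uses_mm), int(params.has_second_predator)


@njit(cache=True)
def _production_rate(L, p, use_mm, literal_counts):
    if L <= 0:
        return 0.0
    if use_mm == 1:
        if literal_counts == 1:
            return p[7] * L / (p[8] + L)
        ell = L / p[6]
        return p[6] * p[7] * ell / (p[8] + ell)
    return p[0] * L


@njit(cache=True)
def ssa_direct(state0, n_gen, seed, p, use_mm, has_s2, literal_counts, out):
    """Exact direct-method SSA, recording the state at integer generations.

    ``out`` has shape (n_gen+1, 4).  The recorded state at generation g is
    the state after the last event at time <= g.  Returns the event count.
    """
    np.random.seed(seed)
    L = state0[0]
    S = state0[1]
    R = state0[2]
    S2 = state0[3]
    t = 0.0
    next_rec = 0
    n_events = 0
    while next_rec <= n_gen:
        a0 = _production_rate(L, p, use_mm, literal_counts)
        a1 = p[1] * R
        a2 = p[2] / p[6] * R * S
        a3 = p[3] * R
        a4 = p[4] * L
        a5 = p[5] * S
        a6 = 0.0
        a7 = 0.0
        if has_s2 == 1:
            a6 = p[9] / p[6] * R * S2
            a7 = p[5] * S2
        atot = a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7
        if atot <= 0.0:
            # absorbing state: fill the remaining grid
            while next_rec <= n_gen:
                out[next_rec, 0] = L
                out[next_rec, 1] = S
                out[next_rec, 2] = R
                out[next_rec, 3] = S2
                next_rec += 1
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        t_next = t - np.log(u) / atot
        while next_rec <= n_gen and next_rec < t_next:
            out[next_rec, 0] = L
            out[next_rec, 1] = S
            out[next_rec, 2] = R
            out[next_rec, 3] = S2
            next_rec += 1
        if next_rec > n_gen:
            break
        t = t_next
        r = np.random.random() * atot
        if r < a0:
            R += 1
        elif r < a0 + a1:
            R -= 1
            L += 1
        elif r < a0 + a1 + a2:
            R -= 1
            S += 1
        elif r < a0 + a1 + a2 + a3:
            R -= 1
        elif r < a0 + a1 + a2 + a3 + a4:
            L -= 1
        elif r < a0 + a1 + a2 + a3 + a4 + a5:
            S -= 1
        elif r < a0 + a1 + a2 + a3 + a4 + a5 + a6:
            R -= 1
            S2 += 1
        else:
            S2 -= 1
        n_events += 1
    return n_events


@njit(cache=True)
def ssa_tau_leap(state0, n_gen, seed, p, use_mm, has_s2, literal_counts, tau, out):
    """Poisson tau-leaping with step halving on negativity.

    Approximate engine for large sweeps; propensities are frozen over each
    leap.  When a drawn update would drive a count negative the leap is
    retried with half the step (down to tau/64, then single-event SSA
    semantics via a one-draw leap).  Returns the number of leaps taken.
    """
    np.random.seed(seed)
    L = state0[0]
    S = state0[1]
    R = state0[2]
    S2 = state0[3]
    t = 0.0
    next_rec = 0
    n_steps = 0
    while next_rec <= n_gen:
        a0 = _production_rate(L, p, use_mm, literal_counts)
        a1 = p[1] * R
        a2 = p[2] / p[6] * R * S
        a3 = p[3] * R
        a4 = p[4] * L
        a5 = p[5] * S
        a6 = 0.0
        a7 = 0.0
        if has_s2 == 1:
            a6 = p[9] / p[6] * R * S2
            a7 = p[5] * S2
        atot = a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7
        if atot <= 0.0:
            while next_rec <= n_gen:
                out[next_rec, 0] = L
                out[next_rec, 1] = S
                out[next_rec, 2] = R
                out[next_rec, 3] = S2
                next_rec += 1
            break
        step = tau
        for _attempt in range(7):
            k0 = np.random.poisson(a0 * step)
            k1 = np.random.poisson(a1 * step)
            k2 = np.random.poisson(a2 * step)
            k3 = np.random.poisson(a3 * step)
            k4 = np.random.poisson(a4 * step)
            k5 = np.random.poisson(a5 * step)
            k6 = np.random.poisson(a6 * step) if has_s2 == 1 else 0
            k7 = np.random.poisson(a7 * step) if has_s2 == 1 else 0
            newL = L + k1 - k4
            newS = S + k2 - k5
            newR = R + k0 - k1 - k2 - k3 - k6
            newS2 = S2 + k6 - k7
            if newL >= 0 and newS >= 0 and newR >= 0 and newS2 >= 0:
                t_next = t + step
                while next_rec <= n_gen and next_rec < t_next:
                    out[next_rec, 0] = L
                    out[next_rec, 1] = S
                    out[next_rec, 2] = R
                    out[next_rec, 3] = S2
                    next_rec += 1
                L = newL
                S = newS
                R = newR
                S2 = newS2
                t = t_next
                break
            step *= 0.5
        else:
            # persistent negativity: take one exact event instead
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            t_next = t - np.log(u) / atot
            while next_rec <= n_gen and next_rec < t_next:
                out[next_rec, 0] = L
                out[next_rec, 1] = S
                out[next_rec, 2] = R
                out[next_rec, 3] = S2
                next_rec += 1
            if next_rec > n_gen:
                break
            t = t_next
            r = np.random.random() * atot
            if r < a0:
                R += 1
            elif r < a0 + a1:
                R -= 1
                L += 1
            elif r < a0 + a1 + a2:
                R -= 1
                S += 1
            elif r < a0 + a1 + a2 + a3:
                R -= 1
            elif r < a0 + a1 + a2 + a3 + a4:
                L -= 1
            elif r < a0 + a1 + a2 + a3 + a4 + a5:
                S -= 1
            elif r < a0 + a1 + a2 + a3 + a4 + a5 + a6:
                R -= 1
                S2 += 1
            else:
                S2 -= 1
        n_steps += 1
    return n_steps
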