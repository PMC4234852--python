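"""Numba kernels: propensity evaluation, exact SSA loops, event-log replay.

Channel indexing is fixed per configuration so that both simulation methods,
the python rule enumerator and the replay/estimator code all agree on what
channel ``c`` means.  With ``n`` nucleosomes and ``P`` connectivity pairs:

====================  =========================  =======================
index                 channel                    enabled when
====================  =========================  =======================
0                     initiate Mt                Mt site empty
1                     initiate At                dual and At site empty
2      .. 2+n-1       unbind(i)                  occ[i] != empty
2+n    .. 2+2n-1      catalyze_site(i)           occ[i] bound, mods[i]=U
2+2n   .. 2+3n-1      catalyze_neighbor(i,i-1)   recruitment mechanisms
2+3n   .. 2+4n-1      catalyze_neighbor(i,i+1)   recruitment mechanisms
2+4n   .. 2+5n-1      slide(i,i-1)               diffusion mechanisms
2+5n   .. 2+6n-1      slide(i,i+1)               diffusion mechanisms
2+6n   .. 2+7n-1      recruit Mt at i            recruitment mechanisms
2+7n   .. 2+8n-1      recruit At at i            dual + recruitment
2+8n   .. 2+9n-1      background_acetylate(i)    single-enzyme model
2+9n   .. 2+10n-1     demodify(i)                mods[i] != U
2+10n  .. 2+10n+P-1   connect(pair j)            >= 1 site occupied
====================  =========================  =======================

Ties between tentative firing times (measure zero, but possible in floating
point) resolve to the smallest channel index in both methods.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# modification / occupancy codes (mirrors nucspread.model)
U, A, M = 0, 1, 2
EMPTY, MT, AT = 0, 1, 2

# rate-vector layout
R_ON, R_OFF, R_CAT, R_NB, R_SLIDE, R_REC, R_DEM, R_BG, R_INT = range(9)

# event kind codes
K_INITIATE, K_UNBIND, K_CAT_SITE, K_CAT_NB, K_SLIDE, K_RECRUIT, K_BG_AC, K_DEMOD, K_CONNECT = range(9)

STATUS_DONE, STATUS_ABSORBED, STATUS_OVERFLOW = 0, 1, 2


@njit(cache=True)
def n_channels(n, n_pairs):
    return 2 + 10 * n + n_pairs


@njit(cache=True)
def fill_propensities(mods, occ, rates, slide_on, recruit_on, dual, site_mt, site_at, pp, qq, a):
    """Write the propensity of every channel (0 if disabled) into ``a``."""
    n = mods.shape[0]
    a[0] = rates[R_ON] if occ[site_mt] == EMPTY else 0.0
    a[1] = rates[R_ON] if (dual and occ[site_at] == EMPTY) else 0.0
    for i in range(n):
        bound = occ[i] != EMPTY
        a[2 + i] = rates[R_OFF] if bound else 0.0
        a[2 + n + i] = rates[R_CAT] if (bound and mods[i] == U) else 0.0
        a[2 + 2 * n + i] = (
            rates[R_NB] if (recruit_on and bound and i > 0 and mods[i - 1] == U) else 0.0
        )
        a[2 + 3 * n + i] = (
            rates[R_NB] if (recruit_on and bound and i < n - 1 and mods[i + 1] == U) else 0.0
        )
        # k_slide is the total hop rate, split over the two directions
        a[2 + 4 * n + i] = (
            0.5 * rates[R_SLIDE] if (slide_on and bound and i > 0 and occ[i - 1] == EMPTY) else 0.0
        )
        a[2 + 5 * n + i] = (
            0.5 * rates[R_SLIDE]
            if (slide_on and bound and i < n - 1 and occ[i + 1] == EMPTY)
            else 0.0
        )
        a[2 + 6 * n + i] = (
            rates[R_REC] if (recruit_on and (not bound) and mods[i] == M) else 0.0
        )
        a[2 + 7 * n + i] = (
            rates[R_REC] if (dual and recruit_on and (not bound) and mods[i] == A) else 0.0
        )
        a[2 + 8 * n + i] = rates[R_BG] if ((not dual) and mods[i] == U) else 0.0
        a[2 + 9 * n + i] = rates[R_DEM] if mods[i] != U else 0.0
    base = 2 + 10 * n
    for j in range(pp.shape[0]):
        a[base + j] = rates[R_INT] if (occ[pp[j]] != EMPTY or occ[qq[j]] != EMPTY) else 0.0
    return a


@njit(cache=True)
def decode_channel(c, n, site_mt, site_at, mods, occ, pp, qq):
    """Map a channel index to (kind, enzyme, pos1, pos2) in the current state."""
    if c == 0:
        return K_INITIATE, MT, site_mt, -1
    if c == 1:
        return K_INITIATE, AT, site_at, -1
    d = c - 2
    if d < 10 * n:
        block = d // n
        i = d % n
        if block == 0:
            return K_UNBIND, occ[i], i, -1
        if block == 1:
            return K_CAT_SITE, occ[i], i, -1
        if block == 2:
            return K_CAT_NB, occ[i], i, i - 1
        if block == 3:
            return K_CAT_NB, occ[i], i, i + 1
        if block == 4:
            return K_SLIDE, occ[i], i, i - 1
        if block == 5:
            return K_SLIDE, occ[i], i, i + 1
        if block == 6:
            return K_RECRUIT, MT, i, -1
        if block == 7:
            return K_RECRUIT, AT, i, -1
        if block == 8:
            return K_BG_AC, EMPTY, i, -1
        return K_DEMOD, EMPTY, i, -1
    j = d - 10 * n
    return K_CONNECT, EMPTY, pp[j], qq[j]


@njit(cache=True)
def apply_event(mods, occ, kind, enzyme, p1, p2):
    """Apply one decoded event in place (shared by SSA loops and replay)."""
    if kind == K_INITIATE or kind == K_RECRUIT:
        occ[p1] = enzyme
    elif kind == K_UNBIND:
        occ[p1] = EMPTY
    elif kind == K_CAT_SITE:
        mods[p1] = M if enzyme == MT else A
    elif kind == K_CAT_NB:
        mods[p2] = M if enzyme == MT else A
    elif kind == K_SLIDE:
        occ[p2] = occ[p1]
        occ[p1] = EMPTY
    elif kind == K_BG_AC:
        mods[p1] = A
    elif kind == K_DEMOD:
        mods[p1] = U
    elif kind == K_CONNECT:
        tmp = occ[p1]
        occ[p1] = occ[p2]
        occ[p2] = tmp


@njit(cache=True)
def run_direct(
    mods, occ, rates, slide_on, recruit_on, dual, site_mt, site_at, pp, qq,
    t_end, seed, times, kinds, enzymes, pos1, pos2,
):
    """Gillespie direct method; records events until t_end or absorption."""
    np.random.seed(seed)
    n = mods.shape[0]
    C = n_channels(n, pp.shape[0])
    a = np.empty(C, dtype=np.float64)
    max_events = times.shape[0]
    t = 0.0
    ne = 0
    while True:
        fill_propensities(mods, occ, rates, slide_on, recruit_on, dual, site_mt, site_at, pp, qq, a)
        total = 0.0
        for c in range(C):
            total += a[c]
        if total <= 0.0:
            return ne, STATUS_ABSORBED
        t += np.random.exponential(1.0) / total
        if t > t_end:
            return ne, STATUS_DONE
        r = np.random.random() * total
        acc = 0.0
        chosen = C - 1
        for c in range(C):
            acc += a[c]
            if r < acc:
                chosen = c
                break
        if ne >= max_events:
            return ne, STATUS_OVERFLOW
        kind, enzyme, p1, p2 = decode_channel(chosen, n, site_mt, site_at, mods, occ, pp, qq)
        apply_event(mods, occ, kind, enzyme, p1, p2)
        times[ne] = t
        kinds[ne] = kind
        enzymes[ne] = enzyme
        pos1[ne] = p1
        pos2[ne] = p2
        ne += 1


@njit(cache=True)
def run_next_reaction(
    mods, occ, rates, slide_on, recruit_on, dual, site_mt, site_at, pp, qq,
    t_end, seed, times, kinds, enzymes, pos1, pos2,
):
    """Next-reaction method: per-channel tentative firing times.

    Channels whose propensity is unchanged by an event keep their scheduled
    time; the fired channel and any channel whose propensity changed draw a
    fresh exponential (exact by the memoryless property).
    """
    np.random.seed(seed)
    n = mods.shape[0]
    C = n_channels(n, pp.shape[0])
    a_old = np.empty(C, dtype=np.float64)
    a_new = np.empty(C, dtype=np.float64)
    tent = np.empty(C, dtype=np.float64)
    max_events = times.shape[0]

    fill_propensities(mods, occ, rates, slide_on, recruit_on, dual, site_mt, site_at, pp, qq, a_old)
    for c in range(C):
        tent[c] = np.random.exponential(1.0) / a_old[c] if a_old[c] > 0.0 else np.inf
    t = 0.0
    ne = 0
    while True:
        chosen = 0
        t_min = tent[0]
        for c in range(1, C):
            if tent[c] < t_min:  # strict: ties go to the smallest index
                t_min = tent[c]
                chosen = c
        if not np.isfinite(t_min):
            return ne, STATUS_ABSORBED
        if t_min > t_end:
            return ne, STATUS_DONE
        if ne >= max_events:
            return ne, STATUS_OVERFLOW
        t = t_min
        kind, enzyme, p1, p2 = decode_channel(chosen, n, site_mt, site_at, mods, occ, pp, qq)
        apply_event(mods, occ, kind, enzyme, p1, p2)
        times[ne] = t
        kinds[ne] = kind
        enzymes[ne] = enzyme
        pos1[ne] = p1
        pos2[ne] = p2
        ne += 1
        fill_propensities(mods, occ, rates, slide_on, recruit_on, dual, site_mt, site_at, pp, qq, a_new)
        for c in range(C):
            if c == chosen or a_new[c] != a_old[c]:
                tent[c] = t + np.random.exponential(1.0) / a_new[c] if a_new[c] > 0.0 else np.inf
            a_old[c] = a_new[c]


# ---------------------------------------------------------------------------
# event-log replay


@njit(cache=True)
def state_at(mods0, occ0, times, kinds, enzymes, pos1, pos2, t):
    """State holding at time t (right-continuous replay of the event log)."""
    mods = mods0.copy()
    occ = occ0.copy()
    for i in range(times.shape[0]):
        if times[i] > t:
            break
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
    return mods, occ


@njit(cache=True)
def snapshot(mods0, occ0, times, kinds, enzymes, pos1, pos2, dt, t_end):
    """Kymograph: rows r = state at r*dt for r = 0 .. floor(t_end/dt)."""
    n = mods0.shape[0]
    rows = int(np.floor(t_end / dt)) + 1
    mods_mat = np.empty((rows, n), dtype=np.int8)
    occ_mat = np.empty((rows, n), dtype=np.int8)
    mods = mods0.copy()
    occ = occ0.copy()
    i = 0
    ne = times.shape[0]
    for r in range(rows):
        t = r * dt
        while i < ne and times[i] <= t:
            apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
            i += 1
        mods_mat[r, :] = mods
        occ_mat[r, :] = occ
    return mods_mat, occ_mat


@njit(cache=True)
def _observables(mods, occ, out):
    """Counts of the six observables: U, A, M, Mt, At, bound enzymes."""
    n = mods.shape[0]
    for k in range(6):
        out[k] = 0.0
    for i in range(n):
        out[mods[i]] += 1.0
        if occ[i] != EMPTY:
            out[2 + occ[i]] += 1.0
            out[5] += 1.0


@njit(cache=True)
def totals_series(mods0, occ0, kinds, enzymes, pos1, pos2):
    """Counts of U/A/M/Mt/At/enzymes after each event ((ne+1, 6), row 0 = t=0)."""
    ne = kinds.shape[0]
    out = np.empty((ne + 1, 6), dtype=np.float64)
    mods = mods0.copy()
    occ = occ0.copy()
    _observables(mods, occ, out[0])
    for i in range(ne):
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        _observables(mods, occ, out[i + 1])
    return out


@njit(cache=True)
def integrate_observables(mods0, occ0, times, kinds, enzymes, pos1, pos2, t_final, t0, t1):
    """Time integral of each observable count over the window [t0, t1].

    ``t_final`` is the trajectory horizon; the last recorded state holds from
    the final event to ``t_final`` (and the window must lie within it).
    """
    mods = mods0.copy()
    occ = occ0.copy()
    ne = times.shape[0]
    i = 0
    while i < ne and times[i] <= t0:
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        i += 1
    acc = np.zeros(6, dtype=np.float64)
    cur = np.empty(6, dtype=np.float64)
    _observables(mods, occ, cur)
    t_prev = t0
    while i < ne and times[i] <= t1:
        dt = times[i] - t_prev
        for k in range(6):
            acc[k] += cur[k] * dt
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        _observables(mods, occ, cur)
        t_prev = times[i]
        i += 1
    dt = t1 - t_prev
    for k in range(6):
        acc[k] += cur[k] * dt
    return acc


@njit(cache=True)
def positional_weights(mods0, occ0, times, kinds, enzymes, pos1, pos2, t0, t1):
    """Per-position time spent in each mod state / occupancy over [t0, t1].

    Returns (mod_w, occ_w): shapes (3, n); mod_w rows are U/A/M, occ_w rows
    empty/Mt/At.  Each column sums to (t1 - t0).
    """
    n = mods0.shape[0]
    mods = mods0.copy()
    occ = occ0.copy()
    ne = times.shape[0]
    i = 0
    while i < ne and times[i] <= t0:
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        i += 1
    mod_w = np.zeros((3, n), dtype=np.float64)
    occ_w = np.zeros((3, n), dtype=np.float64)
    last_mod = np.full(n, t0)
    last_occ = np.full(n, t0)
    while i < ne and times[i] <= t1:
        t = times[i]
        k = kinds[i]
        p1 = pos1[i]
        p2 = pos2[i]
        if k == K_CAT_SITE or k == K_BG_AC or k == K_DEMOD:
            mod_w[mods[p1], p1] += t - last_mod[p1]
            last_mod[p1] = t
        elif k == K_CAT_NB:
            mod_w[mods[p2], p2] += t - last_mod[p2]
            last_mod[p2] = t
        elif k == K_INITIATE or k == K_UNBIND or k == K_RECRUIT:
            occ_w[occ[p1], p1] += t - last_occ[p1]
            last_occ[p1] = t
        elif k == K_SLIDE or k == K_CONNECT:
            occ_w[occ[p1], p1] += t - last_occ[p1]
            last_occ[p1] = t
            occ_w[occ[p2], p2] += t - last_occ[p2]
            last_occ[p2] = t
        apply_event(mods, occ, k, enzymes[i], p1, p2)
        i += 1
    for p in range(n):
        mod_w[mods[p], p] += t1 - last_mod[p]
        occ_w[occ[p], p] += t1 - last_occ[p]
    return mod_w, occ_w


@njit(cache=True)
def count_weights(mods0, occ0, times, kinds, enzymes, pos1, pos2, t0, t1):
    """Time spent at each total count of the six observables over [t0, t1].

    Returns (6, n+1): row k, column v = time with observable k equal to v.
    """
    n = mods0.shape[0]
    mods = mods0.copy()
    occ = occ0.copy()
    ne = times.shape[0]
    i = 0
    while i < ne and times[i] <= t0:
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        i += 1
    w = np.zeros((6, n + 1), dtype=np.float64)
    cur = np.empty(6, dtype=np.float64)
    _observables(mods, occ, cur)
    t_prev = t0
    while i < ne and times[i] <= t1:
        dt = times[i] - t_prev
        for k in range(6):
            w[k, int(cur[k])] += dt
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        _observables(mods, occ, cur)
        t_prev = times[i]
        i += 1
    dt = t1 - t_prev
    for k in range(6):
        w[k, int(cur[k])] += dt
    return w


@njit(cache=True)
def binned_time_averages(mods0, occ0, times, kinds, enzymes, pos1, pos2, t_end, bin_width):
    """Time-weighted mean of each observable per bin ((6, nbins) array).

    Bin b covers [b*bin_width, (b+1)*bin_width); the final partial bin is
    dropped so every reported bin is fully observed.
    """
    nbins = int(np.floor(t_end / bin_width))
    out = np.zeros((6, nbins), dtype=np.float64)
    mods = mods0.copy()
    occ = occ0.copy()
    cur = np.empty(6, dtype=np.float64)
    _observables(mods, occ, cur)
    t_prev = 0.0
    ne = times.shape[0]
    i = 0
    while True:
        t_next = times[i] if i < ne else t_end
        if t_next > t_end:
            t_next = t_end
        # spread the interval [t_prev, t_next) over the bins it covers
        b = int(t_prev / bin_width)
        while b < nbins and b * bin_width < t_next:
            lo = max(t_prev, b * bin_width)
            hi = min(t_next, (b + 1) * bin_width)
            if hi > lo:
                for k in range(6):
                    out[k, b] += cur[k] * (hi - lo)
            b += 1
        if i >= ne or times[i] > t_end:
            break
        apply_event(mods, occ, kinds[i], enzymes[i], pos1[i], pos2[i])
        _observables(mods, occ, cur)
        t_prev = times[i]
        i += 1
    return out / bin_width
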