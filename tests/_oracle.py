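"""Independent brute-force oracles used only by the tests.

``naive_channels`` re-derives the enabled reaction set clause by clause,
written directly from the model rules and deliberately sharing no code with
``nucspread.model.enumerate_enabled_reactions``.  ``generator_matrix``
assembles the explicit CTMC generator on an enumerated state space so the
SSA output can be checked against the exact stationary distribution.
"""

from __future__ import annotations

import itertools

import numpy as np

from nucspread.model import ArrayState


def naive_channels(state, config):
    """Set of (kind, enzyme, positions, propensity) tuples enabled in state."""
    mods = [int(v) for v in state.mods]  # 0=U 1=A 2=M
    occ = [int(v) for v in state.occ]  # 0=empty 1=Mt 2=At
    n = len(mods)
    r = config.rates
    dual = config.enzymes == "dual"
    diffusive = config.mechanism in ("diffusion", "combined")
    recruiting = config.mechanism in ("recruitment", "combined")
    mark_of = {1: 2, 2: 1}  # Mt writes M, At writes A
    name_of = {1: "Mt", 2: "At"}
    out = set()

    # initiation: site must be free, modification state irrelevant
    if occ[config.initiation_sites["Mt"] - 1] == 0:
        out.add(("initiate", "Mt", (config.initiation_sites["Mt"],), r.k_on))
    if dual and occ[config.initiation_sites["At"] - 1] == 0:
        out.add(("initiate", "At", (config.initiation_sites["At"],), r.k_on))

    for i in range(1, n + 1):
        m, o = mods[i - 1], occ[i - 1]
        if o != 0:
            out.add(("unbind", name_of[o], (i,), r.k_off))
            if m == 0:
                out.add(("catalyze_site", name_of[o], (i,), r.k_transferase))
        if recruiting and o != 0:
            if i > 1 and mods[i - 2] == 0:
                out.add(("catalyze_neighbor", name_of[o], (i, i - 1), r.k_neighbor))
            if i < n and mods[i] == 0:
                out.add(("catalyze_neighbor", name_of[o], (i, i + 1), r.k_neighbor))
        if diffusive and o != 0:
            if i > 1 and occ[i - 2] == 0:
                out.add(("slide", name_of[o], (i, i - 1), r.k_slide / 2))
            if i < n and occ[i] == 0:
                out.add(("slide", name_of[o], (i, i + 1), r.k_slide / 2))
        if recruiting and o == 0:
            for enz in (1, 2) if dual else (1,):
                if m == mark_of[enz]:
                    out.add(("recruit", name_of[enz], (i,), r.k_recruitment))
        if not dual and m == 0 and r.k_background_acetylation > 0:
            out.add(("background_acetylate", None, (i,), r.k_background_acetylation))
        if m != 0:
            out.add(("demodify", None, (i,), r.k_demodification))

    sites = list(config.connectivity_sites)
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            p, q = sites[a], sites[b]
            if occ[p - 1] != 0 or occ[q - 1] != 0:
                out.add(("connect", None, (p, q), r.k_interaction))
    return out


def enumerate_state_space(config):
    """All valid (mods, occ) states for a small single- or dual-enzyme model."""
    occ_values = (0, 1, 2) if config.enzymes == "dual" else (0, 1)
    states = []
    for m in itertools.product((0, 1, 2), repeat=config.n):
        for o in itertools.product(occ_values, repeat=config.n):
            states.append(ArrayState(np.array(m, dtype=np.int8), np.array(o, dtype=np.int8)))
    return states


def generator_matrix(config):
    """Explicit CTMC generator over the enumerated state space.

    Returns (states, index, Q) with Q[i, j] the i->j transition rate and
    diagonal entries set to minus the row sums.
    """
    from nucspread.model import apply_reaction, enumerate_enabled_reactions

    states = enumerate_state_space(config)
    index = {(*s.mods, *s.occ): i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    for i, s in enumerate(states):
        for ch in enumerate_enabled_reactions(s, config):
            t = apply_reaction(s, ch)
            Q[i, index[(*t.mods, *t.occ)]] += ch.propensity
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return states, index, Q


def stationary_distribution(Q):
    """Stationary vector of a generator (left null space, normalised)."""
    w, v = np.linalg.eig(Q.T)
    pi = np.real(v[:, np.argmin(np.abs(w))])
    pi = np.abs(pi)
    return pi / pi.sum()


def empirical_state_weights(traj, index):
    """Time-weighted empirical distribution of a trajectory over the space."""
    mods = traj.initial.mods.copy()
    occ = traj.initial.occ.copy()
    from nucspread._kernel import apply_event

    weights = np.zeros(len(index))
    t_prev = 0.0
    for i in range(traj.n_events):
        weights[index[(*mods, *occ)]] += traj.times[i] - t_prev
        apply_event(mods, occ, traj.kinds[i], traj.enzymes[i], traj.pos1[i], traj.pos2[i])
        t_prev = traj.times[i]
    weights[index[(*mods, *occ)]] += traj.t_end - t_prev
    return weights / weights.sum()


def random_state(rng, n, dual):
    mods = rng.integers(0, 3, size=n).astype(np.int8)
    occ = rng.integers(0, 3 if dual else 2, size=n).astype(np.int8)
    return ArrayState(mods, occ)
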