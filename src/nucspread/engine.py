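"""Exact stochastic simulation of the nucleosome-array CTMC.

The default solver is the next-reaction method (per-channel tentative firing
times); the classic direct method is retained as an independently coded
cross-validation oracle.  Both are statistically exact samplers of the chain
defined in :mod:`nucspread.model`, and identical ``(config, seed, method)``
triples reproduce identical event logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from . import _kernel as K
from .model import (
    AT,
    EMPTY,
    MT,
    ArrayState,
    ConfigurationError,
    ModelConfig,
    initial_state,
)

__all__ = [
    "KIND_NAMES",
    "ReactionEvent",
    "Kymograph",
    "Trajectory",
    "simulate",
    "replicate_seed",
    "iter_ensemble",
    "run_ensemble",
]

KIND_NAMES = (
    "initiate",
    "unbind",
    "catalyze_site",
    "catalyze_neighbor",
    "slide",
    "recruit",
    "background_acetylate",
    "demodify",
    "connect",
)
ENZYME_NAMES = {EMPTY: None, MT: "Mt", AT: "At"}

METHODS = ("next_reaction", "direct")


@dataclass(frozen=True)
class ReactionEvent:
    """One fired reaction: time (s), kind, acting enzyme, 1-based positions."""

    time: float
    kind: str
    enzyme: str | None
    positions: tuple


@dataclass
class Kymograph:
    """Regular position x time raster of the array state.

    ``mods`` and ``occ`` are (rows, n) integer matrices with row r sampled at
    ``times[r]``; codes follow :mod:`nucspread.model` (U/A/M -> 0/1/2,
    empty/Mt/At -> 0/1/2).
    """

    times: np.ndarray
    mods: np.ndarray
    occ: np.ndarray


def _pack(config: ModelConfig):
    r = config.rates
    rates = np.array(
        [
            r.k_on,
            r.k_off,
            r.k_transferase,
            r.k_neighbor,
            r.k_slide,
            r.k_recruitment,
            r.k_demodification,
            r.k_background_acetylation,
            r.k_interaction,
        ],
        dtype=np.float64,
    )
    pairs = config.connectivity_pairs()
    pp = np.array([p - 1 for p, _ in pairs], dtype=np.int64)
    qq = np.array([q - 1 for _, q in pairs], dtype=np.int64)
    site_mt = config.initiation_sites["Mt"] - 1
    site_at = config.initiation_sites["At"] - 1 if config.is_dual else -1
    return (
        rates,
        int(config.slide_enabled),
        int(config.recruitment_enabled),
        int(config.is_dual),
        site_mt,
        site_at,
        pp,
        qq,
    )


@dataclass
class Trajectory:
    """A recorded realisation of the model over ``[0, t_end]``.

    The event log (times strictly increasing, channel kind, enzyme and
    0-based kernel positions) together with ``initial`` reconstructs the
    state at any time; queries are right-continuous.
    """

    config: ModelConfig
    seed: int
    method: str
    t_end: float
    initial: ArrayState
    times: np.ndarray
    kinds: np.ndarray
    enzymes: np.ndarray
    pos1: np.ndarray  # 0-based
    pos2: np.ndarray  # 0-based, -1 when the channel names one position

    @property
    def n_events(self) -> int:
        return self.times.size

    def events(self) -> Iterator[ReactionEvent]:
        for i in range(self.n_events):
            positions = (int(self.pos1[i]) + 1,)
            if self.pos2[i] >= 0:
                positions += (int(self.pos2[i]) + 1,)
            yield ReactionEvent(
                float(self.times[i]),
                KIND_NAMES[self.kinds[i]],
                ENZYME_NAMES[int(self.enzymes[i])],
                positions,
            )

    def _log(self):
        return (self.times, self.kinds, self.enzymes, self.pos1, self.pos2)

    def state_at(self, t: float) -> ArrayState:
        """The unique state holding at time ``t`` (right-continuous)."""
        if not 0 <= t <= self.t_end:
            raise ValueError(f"t={t} outside [0, {self.t_end}]")
        mods, occ = K.state_at(self.initial.mods, self.initial.occ, *self._log(), t)
        return ArrayState(mods, occ)

    def final_state(self) -> ArrayState:
        return self.state_at(self.t_end)

    def snapshot_matrix(self, dt: float) -> Kymograph:
        """Sample the state every ``dt`` seconds (floor(t_end/dt)+1 rows)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        mods, occ = K.snapshot(self.initial.mods, self.initial.occ, *self._log(), dt, self.t_end)
        times = np.arange(mods.shape[0]) * dt
        return Kymograph(times, mods, occ)

    def totals(self) -> "pandas.DataFrame":
        """Piecewise-constant totals of U/A/M/Mt/At/enzymes after each event."""
        import pandas as pd

        series = K.totals_series(self.initial.mods, self.initial.occ, *self._log()[1:])
        times = np.concatenate(([0.0], self.times))
        df = pd.DataFrame(series.astype(int), columns=["U", "A", "M", "Mt", "At", "enzymes"])
        df.insert(0, "time", times)
        return df


def _resolve_initial(config: ModelConfig, initial) -> ArrayState:
    if initial is None:
        initial = config.initial_state
    if isinstance(initial, str):
        return initial_state(initial, config)
    if isinstance(initial, ArrayState):
        config.validate_state(initial)
        return initial.copy()
    raise ConfigurationError(f"cannot interpret initial state {initial!r}")


def simulate(
    config: ModelConfig,
    t_end: float,
    seed: int,
    method: str = "next_reaction",
    initial: "ArrayState | str | None" = None,
    _capacity: int = 1 << 16,
) -> Trajectory:
    """Simulate one trajectory of the model CTMC.

    Parameters
    ----------
    config
        Validated model configuration.
    t_end
        Simulation horizon in model seconds (>= 0).  If the chain reaches a
        state with zero total propensity earlier, that state is held to
        ``t_end``.
    seed
        RNG seed; identical (config, seed, method) give identical event logs.
    method
        ``next_reaction`` (default) or ``direct``.
    initial
        Overrides ``config.initial_state`` (preset name or explicit state).
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; use one of {METHODS}")
    state0 = _resolve_initial(config, initial)
    packed = _pack(config)
    runner = K.run_next_reaction if method == "next_reaction" else K.run_direct
    capacity = max(16, int(_capacity))
    while True:
        times = np.empty(capacity, dtype=np.float64)
        kinds = np.empty(capacity, dtype=np.int8)
        enzymes = np.empty(capacity, dtype=np.int8)
        pos1 = np.empty(capacity, dtype=np.int16)
        pos2 = np.empty(capacity, dtype=np.int16)
        ne, status = runner(
            state0.mods.copy(),
            state0.occ.copy(),
            *packed,
            float(t_end),
            int(seed) & 0x7FFFFFFF,
            times,
            kinds,
            enzymes,
            pos1,
            pos2,
        )
        if status != K.STATUS_OVERFLOW:
            break
        capacity *= 2  # rerun from scratch with a bigger buffer (same seed)
    return Trajectory(
        config,
        int(seed),
        method,
        float(t_end),
        state0,
        times[:ne].copy(),
        kinds[:ne].copy(),
        enzymes[:ne].copy(),
        pos1[:ne].copy(),
        pos2[:ne].copy(),
    )


def replicate_seed(master_seed: int, index: int) -> int:
    """Independent per-replicate stream seed derived from (master, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def iter_ensemble(
    config: ModelConfig,
    t_end: float,
    reps: int,
    seed: int,
    method: str = "next_reaction",
    initial=None,
) -> Iterator[Trajectory]:
    """Lazily yield ``reps`` independent replicates (one RNG stream each)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for i in range(reps):
        yield simulate(config, t_end, replicate_seed(seed, i), method=method, initial=initial)


def run_ensemble(
    config: ModelConfig,
    t_end: float,
    reps: int,
    seed: int,
    method: str = "next_reaction",
    initial=None,
) -> list:
    return list(iter_ensemble(config, t_end, reps, seed, method=method, initial=initial))
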