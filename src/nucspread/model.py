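"""Model definition: nucleosome-array state space and reaction channels.

A chromatin region (by default 10 kb, i.e. 50 nucleosomes) is modelled as a 1D
lattice.  Each nucleosome carries exactly one modification state --
acetylated (A), unmodified (U) or methylated (M) -- and can be occupied by at
most one histone-modifying enzyme (a methyltransferase Mt, or in the
dual-enzyme model also an acetyltransferase At).  Enzymes enter the array at a
dedicated initiation site, may slide to free neighbouring nucleosomes (1D
diffusion), may be recruited directly to nucleosomes that already carry their
own mark, catalyse U -> M (or U -> A) on the nucleosome they occupy and, under
the recruitment mechanisms, on unmodified neighbours.  Demodification (M -> U,
A -> U) is a ubiquitous background reaction, as is acetylation of unmodified
nucleosomes in the single-enzyme model.  Optional chromatin-connectivity sites
let enzymes hop or exchange between distant positions.

The continuous-time Markov chain over these states is defined here by
:func:`enumerate_enabled_reactions` / :func:`apply_reaction`; exact stochastic
simulation lives in :mod:`nucspread.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "U",
    "A",
    "M",
    "EMPTY",
    "MT",
    "AT",
    "MECHANISMS",
    "ENZYME_SETS",
    "CONNECTIVITY_LAYOUTS",
    "ConfigurationError",
    "ArrayState",
    "RateSet",
    "ModelConfig",
    "ReactionChannel",
    "enumerate_enabled_reactions",
    "apply_reaction",
    "initial_state",
    "equidistant_positions",
]

# Integer codes for modification states and occupancy.  The same codes are
# used in kymograph TSVs: mods U/A/M -> 0/1/2, occupancy empty/Mt/At -> 0/1/2.
U, A, M = 0, 1, 2
EMPTY, MT, AT = 0, 1, 2

MOD_LETTERS = {U: "U", A: "A", M: "M"}
MOD_CODES = {v: k for k, v in MOD_LETTERS.items()}
OCC_LETTERS = {EMPTY: ".", MT: "Mt", AT: "At"}

#: mark written by each enzyme
ENZYME_MARK = {MT: M, AT: A}

MECHANISMS = ("diffusion", "recruitment", "combined")
ENZYME_SETS = ("single_mt", "dual")

#: equidistant interaction-site layouts on the 50-nucleosome array
CONNECTIVITY_LAYOUTS = {
    2: (15, 35),
    3: (12, 25, 38),
    5: (8, 16, 25, 34, 42),
    10: (3, 8, 13, 18, 23, 28, 33, 38, 43, 48),
}


class ConfigurationError(ValueError):
    """Raised for invalid model configurations or inconsistent states."""


# ---------------------------------------------------------------------------
# state


@dataclass
class ArrayState:
    """Per-nucleosome modification and occupancy of an N-site array.

    Parameters
    ----------
    mods
        Integer modification codes (``U=0, A=1, M=2``), one per nucleosome.
    occ
        Integer occupancy codes (``empty=0, Mt=1, At=2``), one per nucleosome.
    """

    mods: np.ndarray
    occ: np.ndarray

    def __post_init__(self) -> None:
        self.mods = np.asarray(self.mods, dtype=np.int8)
        self.occ = np.asarray(self.occ, dtype=np.int8)
        if self.mods.ndim != 1 or self.occ.shape != self.mods.shape:
            raise ConfigurationError("mods and occ must be 1D arrays of equal length")
        if self.n < 2:
            raise ConfigurationError("array needs at least 2 nucleosomes")
        if not np.isin(self.mods, (U, A, M)).all():
            raise ConfigurationError("invalid modification code")
        if not np.isin(self.occ, (EMPTY, MT, AT)).all():
            raise ConfigurationError("invalid occupancy code")

    @property
    def n(self) -> int:
        return self.mods.size

    def copy(self) -> "ArrayState":
        return ArrayState(self.mods.copy(), self.occ.copy())

    @classmethod
    def from_letters(cls, mods: str, occ: Sequence[str]) -> "ArrayState":
        """Build a state from e.g. ``("AUM...", [".", "Mt", ...])``."""
        m = np.array([MOD_CODES[c] for c in mods], dtype=np.int8)
        rev = {v: k for k, v in OCC_LETTERS.items()}
        o = np.array([rev[c] for c in occ], dtype=np.int8)
        return cls(m, o)

    def mod_letters(self) -> str:
        return "".join(MOD_LETTERS[int(c)] for c in self.mods)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayState):
            return NotImplemented
        return bool(
            np.array_equal(self.mods, other.mods) and np.array_equal(self.occ, other.occ)
        )


# ---------------------------------------------------------------------------
# rates and configuration


@dataclass(frozen=True)
class RateSet:
    """Kinetic rate constants (all s^-1).

    Defaults reproduce the model's reference parameter set: a transferase
    enters the array at its initiation site at ``k_on`` (diffusion-limited,
    2.4 s^-1 in the single-enzyme model, 0.01 s^-1 when two antagonistic
    enzymes compete), detaches at ``k_off`` (10 s residence), modifies its own
    nucleosome essentially instantly (``k_transferase``), its neighbours
    slowly (``k_neighbor``), hops to a free neighbour at a total rate
    ``k_slide`` (split equally left/right), and is recruited to any
    nucleosome carrying its own mark at
    ``k_recruitment``.  Demodification and (single-enzyme model only)
    background acetylation are ubiquitous at 2.4 s^-1.  ``k_interaction``
    applies per connectivity-site pair.
    """

    k_on: float = 2.4
    k_off: float = 0.1
    k_transferase: float = 1000.0
    k_neighbor: float = 0.2
    k_slide: float = 0.6
    k_recruitment: float = 2.4
    k_demodification: float = 2.4
    k_background_acetylation: float = 2.4
    k_interaction: float = 0.1

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(f"rate {name} must be finite and >= 0, got {value}")

    @classmethod
    def table1(cls, enzymes: str = "single_mt", **overrides: float) -> "RateSet":
        """Reference rates; ``k_on`` defaults to 2.4 (single) or 0.01 (dual)."""
        if enzymes not in ENZYME_SETS:
            raise ConfigurationError(f"unknown enzyme set {enzymes!r}")
        kwargs = {"k_on": 2.4 if enzymes == "single_mt" else 0.01}
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def recruitment_efficiency(self) -> float:
        """Modification lifetime over mean time to recruitment (RE)."""
        return self.k_recruitment / self.k_demodification


def _default_initiation(enzymes: str, n: int) -> dict:
    if enzymes == "single_mt":
        # single initiation site in the centre of the array
        return {"Mt": (n + 1) // 2}
    return {"Mt": 5, "At": max(1, n - 5)}


@dataclass(frozen=True)
class ModelConfig:
    """Full specification of one model variant.

    Parameters
    ----------
    n
        Number of nucleosomes (>= 2).
    mechanism
        Transferase movement mechanism: ``diffusion`` (1D sliding only),
        ``recruitment`` (modification-induced recruitment + neighbour
        catalysis, no sliding) or ``combined``.
    enzymes
        ``single_mt`` tracks only the methyltransferase with background
        acetylation; ``dual`` tracks both antagonistic transferases.
    initiation_sites
        1-based position of each enzyme's initiation site.
    connectivity_sites
        1-based positions of chromatin-interaction sites; every unordered
        pair interacts at ``rates.k_interaction``.
    rates
        Kinetic constants; omitted -> reference defaults for ``enzymes``.
    initial_state
        Preset name (``all_A_empty``, ``all_U_empty``, ``all_M_occupied`` or
        ``k_seeds(k)``) resolved by :func:`initial_state`.
    """

    n: int = 50
    mechanism: str = "combined"
    enzymes: str = "single_mt"
    initiation_sites: dict = None  # type: ignore[assignment]
    connectivity_sites: tuple = ()
    rates: RateSet = None  # type: ignore[assignment]
    initial_state: str = "all_A_empty"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if self.enzymes not in ENZYME_SETS:
            raise ConfigurationError(f"unknown enzyme set {self.enzymes!r}")
        if self.rates is None:
            object.__setattr__(self, "rates", RateSet.table1(self.enzymes))
        if self.initiation_sites is None:
            object.__setattr__(self, "initiation_sites", _default_initiation(self.enzymes, self.n))
        sites = dict(self.initiation_sites)
        expected = {"Mt"} if self.enzymes == "single_mt" else {"Mt", "At"}
        if set(sites) != expected:
            raise ConfigurationError(
                f"initiation_sites must name exactly {sorted(expected)}, got {sorted(sites)}"
            )
        for enz, pos in sites.items():
            if not 1 <= int(pos) <= self.n:
                raise ConfigurationError(f"initiation site {enz}@{pos} outside [1, {self.n}]")
        if self.enzymes == "dual" and sites["Mt"] == sites["At"]:
            raise ConfigurationError("dual-enzyme initiation sites must be distinct")
        object.__setattr__(self, "initiation_sites", sites)
        conn = tuple(int(p) for p in self.connectivity_sites)
        if len(set(conn)) != len(conn):
            raise ConfigurationError("connectivity sites must be distinct")
        if any(not 1 <= p <= self.n for p in conn):
            raise ConfigurationError(f"connectivity site outside [1, {self.n}]")
        object.__setattr__(self, "connectivity_sites", conn)

    # convenience -----------------------------------------------------------
    @property
    def is_dual(self) -> bool:
        return self.enzymes == "dual"

    @property
    def slide_enabled(self) -> bool:
        return self.mechanism in ("diffusion", "combined")

    @property
    def recruitment_enabled(self) -> bool:
        """Neighbour catalysis + recruitment binding (recruitment/combined)."""
        return self.mechanism in ("recruitment", "combined")

    @property
    def enzyme_codes(self) -> tuple:
        return (MT,) if self.enzymes == "single_mt" else (MT, AT)

    def with_rates(self, **overrides: float) -> "ModelConfig":
        return replace(self, rates=replace(self.rates, **overrides))

    def connectivity_pairs(self) -> list:
        return list(combinations(self.connectivity_sites, 2))

    def validate_state(self, state: ArrayState) -> None:
        if state.n != self.n:
            raise ConfigurationError(f"state has {state.n} sites, config expects {self.n}")
        if not self.is_dual and (state.occ == AT).any():
            raise ConfigurationError("acetyltransferase present in a single-enzyme model")


# ---------------------------------------------------------------------------
# reaction channels


@dataclass(frozen=True)
class ReactionChannel:
    """One enabled reaction: its kind, acting enzyme, positions and propensity.

    ``positions`` are 1-based; two-position kinds order them as
    (source, target) for ``slide``/``catalyze_neighbor`` and as the two
    interaction sites for ``connect``.
    """

    kind: str
    enzyme: str | None
    positions: tuple
    propensity: float


def _enzyme_name(code: int) -> str:
    return {MT: "Mt", AT: "At"}[code]


def enumerate_enabled_reactions(state: ArrayState, config: ModelConfig) -> list:
    """List every reaction channel enabled in ``state`` with its propensity.

    The rules, in the order channels are reported:

    - ``initiate``: an enzyme binds its (unoccupied) initiation site at
      ``k_on``, regardless of the nucleosome's modification.
    - ``unbind``: any bound enzyme detaches at ``k_off``.
    - ``catalyze_site``: a bound enzyme converts its own U nucleosome to its
      mark at ``k_transferase``.
    - ``catalyze_neighbor`` (recruitment/combined only): a bound enzyme marks
      an unmodified neighbour at ``k_neighbor``; the neighbour's occupancy is
      irrelevant.
    - ``slide`` (diffusion/combined only): a bound enzyme hops to an empty
      neighbouring nucleosome; ``k_slide`` is the total hop rate, split
      equally over the two directions (``k_slide/2`` each) so that the 1D
      mean-squared displacement matches ``k_slide * d^2 * t``.  Array ends
      are reflective and enzymes cannot pass one another.
    - ``recruit`` (recruitment/combined only): an enzyme binds any empty
      nucleosome already carrying its own mark, at ``k_recruitment`` per
      eligible nucleosome.
    - ``background_acetylate`` (single-enzyme model only): any U nucleosome
      acetylates at ``k_background_acetylation``, occupancy-independent.
    - ``demodify``: any A or M nucleosome reverts to U at
      ``k_demodification``, occupancy-independent.
    - ``connect``: each unordered pair of connectivity sites with at least one
      bound enzyme fires at ``k_interaction``; the enzyme hops across (one
      bound) or the two enzymes exchange positions (both bound).
    """
    config.validate_state(state)
    mods, occ, r = state.mods, state.occ, config.rates
    n = config.n
    channels: list = []

    def add(kind: str, enzyme: int | None, positions: tuple, propensity: float) -> None:
        if propensity > 0:
            channels.append(
                ReactionChannel(
                    kind,
                    None if enzyme is None else _enzyme_name(enzyme),
                    positions,
                    propensity,
                )
            )

    # R1 initiation (modification-independent, blocked by any occupant)
    for enz in config.enzyme_codes:
        site = config.initiation_sites[_enzyme_name(enz)]
        if occ[site - 1] == EMPTY:
            add("initiate", enz, (site,), r.k_on)

    for i in range(n):
        e = int(occ[i])
        if e != EMPTY:
            # R2 release
            add("unbind", e, (i + 1,), r.k_off)
            # R3 on-site catalysis
            if mods[i] == U:
                add("catalyze_site", e, (i + 1,), r.k_transferase)
            # R4 neighbour catalysis (target occupancy irrelevant)
            if config.recruitment_enabled:
                for j in (i - 1, i + 1):
                    if 0 <= j < n and mods[j] == U:
                        add("catalyze_neighbor", e, (i + 1, j + 1), r.k_neighbor)
            # R5 sliding to an empty neighbour (k_slide split over directions)
            if config.slide_enabled:
                for j in (i - 1, i + 1):
                    if 0 <= j < n and occ[j] == EMPTY:
                        add("slide", e, (i + 1, j + 1), r.k_slide / 2.0)
        else:
            # R6 recruitment to an empty nucleosome carrying the enzyme's mark
            if config.recruitment_enabled:
                for enz in config.enzyme_codes:
                    if mods[i] == ENZYME_MARK[enz]:
                        add("recruit", enz, (i + 1,), r.k_recruitment)
        # R7 background acetylation (single-enzyme model)
        if not config.is_dual and mods[i] == U:
            add("background_acetylate", None, (i + 1,), r.k_background_acetylation)
        # R8 demodification
        if mods[i] != U:
            add("demodify", None, (i + 1,), r.k_demodification)

    # R9 connectivity
    for p, q in config.connectivity_pairs():
        if occ[p - 1] != EMPTY or occ[q - 1] != EMPTY:
            add("connect", None, (p, q), r.k_interaction)

    return channels


def apply_reaction(
    state: ArrayState, channel: ReactionChannel, config: ModelConfig | None = None, *, validate: bool = False
) -> ArrayState:
    """Return the state after ``channel`` fires.

    Updates are deterministic given the channel.  With ``validate=True`` the
    channel is checked to be currently enabled under ``config`` (requires
    ``config``); use this in debugging, it is O(channels).
    """
    if validate:
        if config is None:
            raise ValueError("validate=True requires config")
        enabled = {
            (c.kind, c.enzyme, c.positions) for c in enumerate_enabled_reactions(state, config)
        }
        if (channel.kind, channel.enzyme, channel.positions) not in enabled:
            raise ValueError(f"channel not enabled in this state: {channel}")

    new = state.copy()
    mods, occ = new.mods, new.occ
    pos = tuple(p - 1 for p in channel.positions)
    enz = {None: EMPTY, "Mt": MT, "At": AT}[channel.enzyme]
    kind = channel.kind
    if kind in ("initiate", "recruit"):
        occ[pos[0]] = enz
    elif kind == "unbind":
        occ[pos[0]] = EMPTY
    elif kind == "catalyze_site":
        mods[pos[0]] = ENZYME_MARK[enz]
    elif kind == "catalyze_neighbor":
        mods[pos[1]] = ENZYME_MARK[enz]
    elif kind == "slide":
        occ[pos[1]] = occ[pos[0]]
        occ[pos[0]] = EMPTY
    elif kind == "background_acetylate":
        mods[pos[0]] = A
    elif kind == "demodify":
        mods[pos[0]] = U
    elif kind == "connect":
        occ[pos[0]], occ[pos[1]] = occ[pos[1]], occ[pos[0]]
    else:
        raise ConfigurationError(f"unknown channel kind {kind!r}")
    return new


# ---------------------------------------------------------------------------
# initial-state presets


def equidistant_positions(n: int, k: int) -> list:
    """k symmetrically spaced 1-based positions: round(n*(2i-1)/(2k))."""
    if not 1 <= k <= n:
        raise ConfigurationError(f"need 1 <= k <= n, got k={k}, n={n}")
    pos = [max(1, min(n, int(np.floor(n * (2 * i - 1) / (2 * k) + 0.5)))) for i in range(1, k + 1)]
    if len(set(pos)) != k:
        raise ConfigurationError(f"equidistant positions collide for n={n}, k={k}")
    return pos


def initial_state(preset: str, config: ModelConfig) -> ArrayState:
    """Resolve an initial-state preset for ``config``.

    - ``all_A_empty``: fully acetylated, no enzymes bound.
    - ``all_U_empty``: fully unmodified, no enzymes bound.
    - ``all_M_occupied``: fully methylated, every nucleosome bound by Mt.
    - ``k_seeds(k)``: all U except ``k`` equidistant methylated nucleosomes,
      each occupied by a methyltransferase.
    """
    n = config.n
    mods = np.full(n, U, dtype=np.int8)
    occ = np.full(n, EMPTY, dtype=np.int8)
    if preset == "all_A_empty":
        mods[:] = A
    elif preset == "all_U_empty":
        pass
    elif preset == "all_M_occupied":
        mods[:] = M
        occ[:] = MT
    elif preset.startswith("k_seeds(") and preset.endswith(")"):
        try:
            k = int(preset[len("k_seeds(") : -1])
        except ValueError as exc:
            raise ConfigurationError(f"bad seed count in preset {preset!r}") from exc
        for p in equidistant_positions(n, k):
            mods[p - 1] = M
            occ[p - 1] = MT
    else:
        raise ConfigurationError(f"unknown initial-state preset {preset!r}")
    return ArrayState(mods, occ)
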