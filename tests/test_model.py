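"""Reaction-rule surface: channel enumeration, state updates, presets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucspread.model import (
    A,
    AT,
    EMPTY,
    M,
    MT,
    U,
    ArrayState,
    ConfigurationError,
    ModelConfig,
    RateSet,
    ReactionChannel,
    apply_reaction,
    enumerate_enabled_reactions,
    equidistant_positions,
    initial_state,
)

from _oracle import naive_channels, random_state
from conftest import all_variants, make_config


class TestChannelCensus:
    def test_all_unmodified_no_enzymes(self):
        """Only initiation and background acetylation fire on a bare array."""
        cfg = ModelConfig(n=50, mechanism="diffusion", enzymes="single_mt",
                          initiation_sites={"Mt": 25})
        state = initial_state("all_U_empty", cfg)
        channels = enumerate_enabled_reactions(state, cfg)
        kinds = sorted(c.kind for c in channels)
        assert kinds.count("initiate") == 1
        assert kinds.count("background_acetylate") == 50
        assert len(channels) == 51
        assert sum(c.propensity for c in channels) == pytest.approx(51 * 2.4)

    def test_saturated_methylated_array(self):
        """A fully methylated, fully occupied array can only unbind or demodify."""
        cfg = ModelConfig(n=50, mechanism="combined", enzymes="single_mt",
                          initiation_sites={"Mt": 25})
        state = initial_state("all_M_occupied", cfg)
        channels = enumerate_enabled_reactions(state, cfg)
        by_kind = {}
        for c in channels:
            by_kind.setdefault(c.kind, []).append(c)
        assert set(by_kind) == {"unbind", "demodify"}
        assert len(by_kind["unbind"]) == 50
        assert len(by_kind["demodify"]) == 50

    def test_slide_rate_split_over_directions(self):
        """An interior enzyme with two free flanks carries k_slide in total."""
        cfg = make_config(n=5, mechanism="diffusion")
        state = ArrayState(np.zeros(5, np.int8), np.array([0, 0, 1, 0, 0], np.int8))
        slides = [c for c in enumerate_enabled_reactions(state, cfg) if c.kind == "slide"]
        assert len(slides) == 2
        assert sum(c.propensity for c in slides) == pytest.approx(cfg.rates.k_slide)

    def test_initiation_blocked_by_occupant(self):
        cfg = make_config(n=5, mechanism="diffusion", enzymes="dual")
        occ = np.zeros(5, np.int8)
        occ[0] = AT  # antagonist parked on the Mt initiation site
        state = ArrayState(np.zeros(5, np.int8), occ)
        inits = [c for c in enumerate_enabled_reactions(state, cfg) if c.kind == "initiate"]
        assert [c.enzyme for c in inits] == ["At"]

    def test_connectivity_pair_needs_an_enzyme(self):
        cfg = make_config(n=6, mechanism="recruitment", enzymes="dual",
                          connectivity=(2, 4, 6))
        empty = ArrayState(np.zeros(6, np.int8), np.zeros(6, np.int8))
        assert not [c for c in enumerate_enabled_reactions(empty, cfg) if c.kind == "connect"]
        occ = np.zeros(6, np.int8)
        occ[1] = MT
        one = ArrayState(np.zeros(6, np.int8), occ)
        pairs = {c.positions for c in enumerate_enabled_reactions(one, cfg) if c.kind == "connect"}
        assert pairs == {(2, 4), (2, 6)}


class TestApplyReaction:
    @pytest.mark.parametrize(
        "kind,enzyme,positions,occ_before,occ_after,mods_delta",
        [
            ("slide", "Mt", (3, 4), [0, 0, 1, 0], [0, 0, 0, 1], {}),
            ("demodify", None, (2,), [0, 1, 0, 0], [0, 1, 0, 0], {2: U}),
            ("catalyze_neighbor", "At", (2, 1), [0, 2, 0, 0], [0, 2, 0, 0], {1: A}),
            ("recruit", "Mt", (4,), [0, 0, 0, 0], [0, 0, 0, 1], {}),
            ("unbind", "At", (2,), [0, 2, 0, 0], [0, 0, 0, 0], {}),
        ],
    )
    def test_deterministic_updates(self, kind, enzyme, positions, occ_before, occ_after, mods_delta):
        mods = np.array([U, M, U, U], np.int8)
        state = ArrayState(mods, np.array(occ_before, np.int8))
        new = apply_reaction(state, ReactionChannel(kind, enzyme, tuple(positions), 1.0))
        assert list(new.occ) == occ_after
        expected = mods.copy()
        for pos, value in mods_delta.items():
            expected[pos - 1] = value
        assert list(new.mods) == list(expected)
        # original untouched
        assert list(state.occ) == occ_before

    def test_connect_exchanges_enzymes_not_marks(self):
        """Chromatin contact swaps the transferases, never the modifications."""
        mods = np.array([M] * 40 + [A] * 10, np.int8)
        occ = np.zeros(50, np.int8)
        occ[14], occ[34] = MT, AT
        state = ArrayState(mods, occ)
        new = apply_reaction(state, ReactionChannel("connect", None, (15, 35), 0.1))
        assert new.occ[14] == AT and new.occ[34] == MT
        assert np.array_equal(new.mods, mods)

    def test_validate_rejects_disabled_channel(self):
        cfg = make_config(n=4, mechanism="diffusion")
        state = ArrayState(np.zeros(4, np.int8), np.array([1, 1, 0, 0], np.int8))
        blocked = ReactionChannel("slide", "Mt", (1, 2), 0.3)  # target occupied
        with pytest.raises(ValueError, match="not enabled"):
            apply_reaction(state, blocked, cfg, validate=True)


class TestInitialState:
    def test_presets(self):
        cfg = ModelConfig(n=50, mechanism="combined", initiation_sites={"Mt": 25})
        s = initial_state("all_M_occupied", cfg)
        assert (s.mods == M).all() and (s.occ == MT).all()
        s = initial_state("all_A_empty", cfg)
        assert (s.mods == A).all() and (s.occ == EMPTY).all()

    @pytest.mark.parametrize("k,expected", [(1, [25]), (2, [13, 38]), (5, [5, 15, 25, 35, 45])])
    def test_equidistant_seeds(self, k, expected):
        assert equidistant_positions(50, k) == expected
        cfg = ModelConfig(n=50, mechanism="combined", initiation_sites={"Mt": 25})
        s = initial_state(f"k_seeds({k})", cfg)
        seeded = [i + 1 for i in range(50) if s.mods[i] == M]
        assert seeded == expected
        assert all(s.occ[p - 1] == MT for p in expected)
        assert (s.mods != M).sum() == 50 - k and ((s.mods == M) == (s.occ == MT)).all()

    def test_full_seeding_is_all_m_occupied(self):
        cfg = ModelConfig(n=50, mechanism="combined", initiation_sites={"Mt": 25})
        assert initial_state("k_seeds(50)", cfg) == initial_state("all_M_occupied", cfg)

    def test_too_many_seeds_rejected(self):
        cfg = ModelConfig(n=50, mechanism="combined", initiation_sites={"Mt": 25})
        with pytest.raises(ConfigurationError):
            initial_state("k_seeds(51)", cfg)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mechanism": "teleport"},
            {"enzymes": "triple"},
            {"n": 1},
            {"initiation_sites": {"Mt": 60}},
            {"enzymes": "dual", "initiation_sites": {"Mt": 5, "At": 5}},
            {"connectivity_sites": (3, 3)},
            {"connectivity_sites": (0,)},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        defaults = dict(n=50, mechanism="combined", enzymes="single_mt")
        defaults.update(kwargs)
        with pytest.raises(ConfigurationError):
            ModelConfig(**defaults)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            RateSet(k_on=-1.0)

    def test_state_config_mismatch(self):
        cfg = make_config(n=6)
        wrong = ArrayState(np.zeros(5, np.int8), np.zeros(5, np.int8))
        with pytest.raises(ConfigurationError):
            enumerate_enabled_reactions(wrong, cfg)

    def test_at_in_single_enzyme_model_rejected(self):
        cfg = make_config(n=4, enzymes="single_mt")
        bad = ArrayState(np.zeros(4, np.int8), np.array([0, 2, 0, 0], np.int8))
        with pytest.raises(ConfigurationError):
            enumerate_enabled_reactions(bad, cfg)


class TestOracleEquivalence:
    """The enumerator must match an independent clause-by-clause oracle."""

    @pytest.mark.parametrize("config", all_variants(), ids=lambda c: f"{c.mechanism}-{c.enzymes}-{len(c.connectivity_sites)}conn")
    def test_random_states_match_naive_enumerator(self, config, rng):
        for _ in range(1500):
            n = int(rng.integers(2, 9))
            cfg = make_config(
                n=n,
                mechanism=config.mechanism,
                enzymes=config.enzymes,
                connectivity=tuple(p for p in config.connectivity_sites if p <= n),
            )
            state = random_state(rng, n, cfg.is_dual)
            if not cfg.is_dual:
                state.occ[state.occ == AT] = MT
            ours = {(c.kind, c.enzyme, c.positions, round(c.propensity, 12))
                    for c in enumerate_enabled_reactions(state, cfg)}
            oracle = {(k, e, p, round(a, 12)) for k, e, p, a in naive_channels(state, cfg)}
            assert ours == oracle


@st.composite
def state_and_config(draw):
    n = draw(st.integers(2, 8))
    mechanism = draw(st.sampled_from(["diffusion", "recruitment", "combined"]))
    enzymes = draw(st.sampled_from(["single_mt", "dual"]))
    conn = draw(st.sets(st.integers(1, n), max_size=4))
    cfg = make_config(n=n, mechanism=mechanism, enzymes=enzymes, connectivity=tuple(sorted(conn)))
    mods = draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
    occ = draw(st.lists(st.integers(0, 2 if enzymes == "dual" else 1), min_size=n, max_size=n))
    state = ArrayState(np.array(mods, np.int8), np.array(occ, np.int8))
    return state, cfg


@settings(max_examples=200, deadline=None, derandomize=True)
@given(state_and_config())
def test_closure_under_every_enabled_channel(sc):
    """Applying any enabled channel yields a valid state changing only the
    channel's named positions."""
    state, cfg = sc
    for ch in enumerate_enabled_reactions(state, cfg):
        new = apply_reaction(state, ch, cfg, validate=True)
        assert new.n == state.n  # constructor re-validates invariants
        touched = {p - 1 for p in ch.positions}
        for i in range(state.n):
            if i not in touched:
                assert new.mods[i] == state.mods[i] and new.occ[i] == state.occ[i]
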