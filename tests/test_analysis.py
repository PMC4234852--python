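"""Time-weighted estimators: hand-computed oracles on toy trajectories,
consistency on analytically solvable processes, recording-mode invariance."""

import numpy as np
import pandas as pd
import pytest

from nucspread.analysis import (
    BinnedDynamics,
    binned_dynamics,
    boundary_statistic,
    count_distribution,
    establishment_time,
    positional_profile,
    relaxation_experiment,
    seeding_experiment,
    switching_summary,
)
from nucspread.engine import Kymograph, Trajectory, simulate
from nucspread.model import A, M, MT, U, ArrayState, ModelConfig, RateSet, initial_state

from conftest import make_config

KIND = {"demodify": 7, "background_acetylate": 6, "unbind": 1}


def make_traj(cfg, initial, events, t_end):
    """Hand-built trajectory from (time, kind, enzyme, pos1, pos2) tuples."""
    events = sorted(events)
    return Trajectory(
        config=cfg,
        seed=0,
        method="next_reaction",
        t_end=float(t_end),
        initial=initial,
        times=np.array([e[0] for e in events], dtype=np.float64),
        kinds=np.array([e[1] for e in events], dtype=np.int8),
        enzymes=np.array([e[2] for e in events], dtype=np.int8),
        pos1=np.array([e[3] for e in events], dtype=np.int16),
        pos2=np.array([e[4] for e in events], dtype=np.int16),
    )


@pytest.fixture
def frozen_all_m():
    cfg = make_config(n=4, mechanism="combined")
    return make_traj(cfg, initial_state("all_M_occupied", cfg), [], 100.0)


class TestPositionalProfile:
    def test_frozen_methylated_array_is_certain(self, frozen_all_m):
        prof = positional_profile([frozen_all_m])
        assert (prof["P_M"] == 1.0).all()
        assert (prof["P_Mt"] == 1.0).all()
        assert (prof["P_A"] == 0.0).all() and (prof["P_U"] == 0.0).all()

    def test_two_interval_trajectory_weights_by_time(self):
        """State X for 30 s then Y for 70 s -> 0.3/0.7 mixture."""
        cfg = make_config(n=3, mechanism="combined")
        initial = ArrayState(np.array([M, M, U], np.int8), np.zeros(3, np.int8))
        traj = make_traj(cfg, initial, [(30.0, KIND["demodify"], 0, 1, -1)], 100.0)
        prof = positional_profile([traj], steady_fraction=1.0)
        assert prof.loc[2, "P_M"] == pytest.approx(0.3)
        assert prof.loc[2, "P_U"] == pytest.approx(0.7)
        assert prof.loc[1, "P_M"] == pytest.approx(1.0)

    def test_probabilities_normalise_on_simulated_run(self):
        cfg = make_config(n=6, mechanism="combined")
        traj = simulate(cfg, 30.0, seed=3)
        prof = positional_profile([traj])
        np.testing.assert_allclose(prof[["P_M", "P_A", "P_U"]].sum(axis=1), 1.0, atol=1e-9)
        assert ((prof[["P_Mt", "P_At"]] >= 0) & (prof[["P_Mt", "P_At"]] <= 1)).all().all()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            positional_profile([])


class TestCountDistribution:
    def test_frozen_array_is_point_mass(self, frozen_all_m):
        dist = count_distribution([frozen_all_m], "M")
        assert dist.sum() == pytest.approx(1.0)
        assert dist.loc[4] == pytest.approx(1.0)

    def test_two_interval_two_point_mass(self):
        cfg = make_config(n=3, mechanism="combined")
        initial = ArrayState(np.array([M, M, U], np.int8), np.zeros(3, np.int8))
        traj = make_traj(cfg, initial, [(30.0, KIND["demodify"], 0, 1, -1)], 100.0)
        dist = count_distribution([traj], "M", steady_fraction=1.0)
        assert dist.loc[2] == pytest.approx(0.3)
        assert dist.loc[1] == pytest.approx(0.7)

    def test_unknown_species_rejected(self, frozen_all_m):
        with pytest.raises(ValueError):
            count_distribution([frozen_all_m], "X")


class TestBinnedDynamics:
    def test_identical_traces_collapse_order_statistics(self, frozen_all_m):
        b = binned_dynamics([frozen_all_m, frozen_all_m, frozen_all_m], "M")
        assert (b.table["min"] == b.table["max"]).all()
        assert (b.table["median"] == 4).all()

    def test_hand_computed_quartiles(self):
        """Constant traces with totals 0, 2 and 4 -> quartiles 1, 2, 3."""
        cfg = make_config(n=4, mechanism="combined")
        trajs = [
            make_traj(cfg, initial_state("all_U_empty", cfg), [], 10.0),
            make_traj(cfg, ArrayState(np.array([M, M, U, U], np.int8),
                                      np.zeros(4, np.int8)), [], 10.0),
            make_traj(cfg, initial_state("all_M_occupied", cfg), [], 10.0),
        ]
        b = binned_dynamics(trajs, "M")
        assert (b.table["q25"] == 1.0).all()
        assert (b.table["median"] == 2.0).all()
        assert (b.table["q75"] == 3.0).all()
        assert (b.table["min"] == 0.0).all() and (b.table["max"] == 4.0).all()

    def test_partial_interval_weighting_within_bin(self):
        """An event at t=0.25 makes the first 1-s bin a 0.25/0.75 mixture."""
        cfg = make_config(n=2, mechanism="combined")
        initial = ArrayState(np.array([M, U], np.int8), np.zeros(2, np.int8))
        traj = make_traj(cfg, initial, [(0.25, KIND["demodify"], 0, 0, -1)], 5.0)
        b = binned_dynamics([traj], "M")
        assert b.values[0, 0] == pytest.approx(0.25)
        assert b.values[0, 1:] == pytest.approx(0.0)

    def test_bad_arguments_rejected(self, frozen_all_m):
        with pytest.raises(ValueError):
            binned_dynamics([frozen_all_m], "bogus")
        with pytest.raises(ValueError):
            binned_dynamics([frozen_all_m], "M", bin_width=0.0)
        with pytest.raises(ValueError):
            binned_dynamics([frozen_all_m], "M", t_max=1000.0)


class TestEstablishmentTime:
    def test_ramp_then_plateau(self):
        med = np.concatenate([np.linspace(0, 40, 100), np.full(100, 40.0)])
        table = pd.DataFrame({
            "time": np.arange(200.0), "min": med, "q25": med,
            "median": med, "q75": med, "max": med,
        })
        b = BinnedDynamics("M", 1.0, table, med[None, :])
        t90, plateau = establishment_time(b)
        assert plateau == pytest.approx(40.0)
        assert t90 == pytest.approx(89.0, abs=1.0)  # first bin with median >= 36


class TestRelaxation:
    def test_without_demodification_methylation_is_conserved(self):
        cfg = make_config(n=10, mechanism="combined", k_off=0.0, k_demodification=0.0)
        b = relaxation_experiment(cfg, reps=3, t_end=20.0, seed=5)
        assert (b.table["min"] == 10).all() and (b.table["max"] == 10).all()

    def test_reps_must_be_positive(self):
        with pytest.raises(ValueError):
            relaxation_experiment(make_config(), reps=0, t_end=1.0, seed=1)


class TestSeeding:
    def test_fully_seeded_stable_regime_always_ends_high(self):
        cfg = ModelConfig(n=50, mechanism="combined", initiation_sites={"Mt": 25},
                          rates=RateSet.table1("single_mt", k_recruitment=2.4, k_on=0.0))
        res = seeding_experiment(cfg, k_seeds=50, reps=6, t_end=60.0, seed=77)
        assert res.fraction == 1.0
        assert res.high_state_mean_m > 25
        assert res.ci_low <= res.fraction <= res.ci_high

    def test_reps_must_be_positive(self):
        with pytest.raises(ValueError):
            seeding_experiment(make_config(n=50), 1, reps=0, t_end=1.0, seed=1)


class TestBoundaryStatistic:
    def test_frozen_opposite_replicates_split_the_mass(self):
        cfg = make_config(n=4, mechanism="combined", enzymes="dual")
        all_m = make_traj(cfg, ArrayState(np.full(4, M, np.int8),
                                          np.zeros(4, np.int8)), [], 20.0)
        all_a = make_traj(cfg, ArrayState(np.full(4, A, np.int8),
                                          np.zeros(4, np.int8)), [], 20.0)
        table = boundary_statistic([all_m, all_a], window=5.0, window_starts=(0.0, 10.0))
        for t0 in (0.0, 10.0):
            sub = table[table["window_start"] == t0].set_index("delta")["probability"]
            assert sub.loc[4] == pytest.approx(0.5)
            assert sub.loc[-4] == pytest.approx(0.5)

    def test_point_mass_for_identical_methylated_replicates(self):
        cfg = make_config(n=4, mechanism="combined", enzymes="dual")
        trajs = [make_traj(cfg, ArrayState(np.full(4, M, np.int8),
                                           np.zeros(4, np.int8)), [], 20.0)
                 for _ in range(3)]
        table = boundary_statistic(trajs, window=10.0, window_starts=(0.0,))
        assert table.loc[0, "delta"] == 4 and table.loc[0, "probability"] == 1.0

    def test_window_beyond_horizon_rejected(self):
        cfg = make_config(n=4, enzymes="dual")
        trajs = [make_traj(cfg, initial_state("all_U_empty", cfg), [], 20.0)] * 2
        with pytest.raises(ValueError):
            boundary_statistic(trajs, window=10.0, window_starts=(15.0,))


class TestSwitchingSummary:
    def test_majority_regions_detected_from_raster(self):
        mods = np.zeros((3, 10), np.int8)
        mods[0, :] = M  # delta +10
        mods[1, :5] = A  # mixed
        mods[2, :] = A  # delta -10
        kymo = Kymograph(np.arange(3.0), mods, np.zeros_like(mods))
        row = switching_summary([kymo]).iloc[0]
        assert row["visited_m"] and row["visited_a"] and row["switched"]


class TestEstimatorConsistency:
    def test_background_telegraph_converges_to_half(self):
        """With only background acetylation and demodification (both 2.4/s)
        each nucleosome is U half the time; error shrinks ~1/sqrt(T)."""
        cfg = make_config(n=2, mechanism="diffusion", k_on=0.0)
        errors = []
        for t_end in (500.0, 5e4):
            traj = simulate(cfg, t_end, seed=99, initial="all_U_empty")
            prof = positional_profile([traj], steady_fraction=1.0)
            errors.append(abs(prof["P_U"].mean() - 0.5))
        assert errors[1] < errors[0]
        assert errors[1] < 0.01

    def test_event_log_and_fine_raster_recordings_agree(self):
        """Estimators give the same answers whether fed the exact event log
        or a fine fixed-step snapshot of the same trajectory."""
        cfg = make_config(n=4, mechanism="combined")
        traj = simulate(cfg, 20.0, seed=21)
        kymo = traj.snapshot_matrix(0.001)
        p_t = positional_profile([traj], steady_fraction=0.6)
        p_k = positional_profile([kymo], steady_fraction=0.6)
        np.testing.assert_allclose(p_t.values, p_k.values, atol=0.02)
        c_t = count_distribution([traj], "M")
        c_k = count_distribution([kymo], "M")
        np.testing.assert_allclose(c_t.values, c_k.values, atol=0.02)
        b_t = binned_dynamics([traj], "M").values
        b_k = binned_dynamics([kymo], "M").values
        np.testing.assert_allclose(b_t, b_k, atol=0.05)
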