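"""Ensemble statistics over simulated trajectories.

All estimators are time-weighted: a state contributes in proportion to the
time the trajectory spends in it, not to the number of recorded events.
Steady-state quantities are evaluated over the final fraction (default 60%)
of each trajectory; dynamics are summarised per 1-s bin by order statistics
(min, quartiles, median, max) across the ensemble.

Estimators accept event-logged :class:`~nucspread.engine.Trajectory` objects
or fixed-step :class:`~nucspread.engine.Kymograph` rasters; the two agree as
the raster step approaches the event resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernel as K
from .engine import Kymograph, Trajectory, iter_ensemble
from .model import ModelConfig

__all__ = [
    "OBSERVABLES",
    "BinnedDynamics",
    "SeedingResult",
    "positional_profile",
    "count_distribution",
    "binned_dynamics",
    "establishment_time",
    "relaxation_experiment",
    "seeding_experiment",
    "boundary_statistic",
    "switching_summary",
]

#: observable name -> row in the kernel's count arrays
OBSERVABLES = {"U": 0, "A": 1, "M": 2, "Mt": 3, "At": 4, "enzymes": 5}


def _as_list(ensemble) -> list:
    if isinstance(ensemble, (Trajectory, Kymograph)):
        return [ensemble]
    items = list(ensemble)
    if not items:
        raise ValueError("empty ensemble")
    return items


def _traj_log(traj: Trajectory):
    return (
        traj.initial.mods,
        traj.initial.occ,
        traj.times,
        traj.kinds,
        traj.enzymes,
        traj.pos1,
        traj.pos2,
    )


def _horizon(item) -> float:
    if isinstance(item, Trajectory):
        return item.t_end
    return float(item.times[-1])


def _n_sites(item) -> int:
    return item.initial.n if isinstance(item, Trajectory) else item.mods.shape[1]


def _kymo_row_weights(kymo: Kymograph, t0: float, t1: float) -> np.ndarray:
    """Duration each raster row holds within [t0, t1] (rows hold for one step)."""
    times = kymo.times
    dt = times[1] - times[0] if times.size > 1 else t1 - t0
    starts = times
    ends = np.append(times[1:], times[-1] + dt)
    return np.clip(np.minimum(ends, t1) - np.maximum(starts, t0), 0.0, None)


def _positional_weights(item, t0: float, t1: float):
    if isinstance(item, Trajectory):
        return K.positional_weights(*_traj_log(item), t0, t1)
    w = _kymo_row_weights(item, t0, t1)
    n = item.mods.shape[1]
    mod_w = np.zeros((3, n))
    occ_w = np.zeros((3, n))
    for s in range(3):
        mod_w[s] = w @ (item.mods == s)
        occ_w[s] = w @ (item.occ == s)
    return mod_w, occ_w


def _count_weights(item, t0: float, t1: float) -> np.ndarray:
    n = _n_sites(item)
    if isinstance(item, Trajectory):
        return K.count_weights(*_traj_log(item), t0, t1)
    w = _kymo_row_weights(item, t0, t1)
    counts = np.empty((len(w), 6), dtype=np.int64)
    for s in range(3):
        counts[:, s] = (item.mods == s).sum(axis=1)
        if s:
            counts[:, 2 + s] = (item.occ == s).sum(axis=1)
    counts[:, 5] = (item.occ != 0).sum(axis=1)
    out = np.zeros((6, n + 1))
    for k in range(6):
        np.add.at(out[k], counts[:, k], w)
    return out


def _steady_window(item, steady_fraction: float):
    if not 0 < steady_fraction <= 1:
        raise ValueError("steady_fraction must be in (0, 1]")
    t_end = _horizon(item)
    return t_end * (1.0 - steady_fraction), t_end


def positional_profile(ensemble, steady_fraction: float = 0.6) -> pd.DataFrame:
    """Time-weighted per-position probabilities at steady state.

    For each trajectory the final ``steady_fraction`` of the horizon is used;
    the per-position probability of each modification (and of occupancy by
    each transferase) is the time spent in that state divided by the window
    length, averaged over the ensemble.

    Returns a DataFrame indexed by 1-based position with columns
    ``P_M, P_A, P_U, P_Mt, P_At``.
    """
    items = _as_list(ensemble)
    n = _n_sites(items[0])
    mod_acc = np.zeros((3, n))
    occ_acc = np.zeros((3, n))
    for item in items:
        t0, t1 = _steady_window(item, steady_fraction)
        mod_w, occ_w = _positional_weights(item, t0, t1)
        span = t1 - t0
        mod_acc += mod_w / span
        occ_acc += occ_w / span
    mod_acc /= len(items)
    occ_acc /= len(items)
    return pd.DataFrame(
        {
            "P_M": mod_acc[2],
            "P_A": mod_acc[1],
            "P_U": mod_acc[0],
            "P_Mt": occ_acc[1],
            "P_At": occ_acc[2],
        },
        index=pd.RangeIndex(1, n + 1, name="position"),
    )


def count_distribution(ensemble, species: str = "M", steady_fraction: float = 0.6) -> pd.Series:
    """Time-weighted steady-state distribution of a total count (0..n).

    ``species`` is one of ``U, A, M, Mt, At, enzymes``.
    """
    if species not in OBSERVABLES:
        raise ValueError(f"unknown species {species!r}; use one of {sorted(OBSERVABLES)}")
    items = _as_list(ensemble)
    n = _n_sites(items[0])
    acc = np.zeros(n + 1)
    for item in items:
        t0, t1 = _steady_window(item, steady_fraction)
        acc += _count_weights(item, t0, t1)[OBSERVABLES[species]] / (t1 - t0)
    acc /= len(items)
    return pd.Series(acc, index=pd.RangeIndex(0, n + 1, name="count"), name=f"P_{species}")


@dataclass
class BinnedDynamics:
    """Per-bin ensemble order statistics of a total count.

    ``table`` has columns ``time`` (bin start), ``min``, ``q25``, ``median``,
    ``q75``, ``max``; quartiles use linear interpolation between order
    statistics.  ``values`` holds the underlying (reps, nbins) matrix of
    per-trajectory time-weighted bin means.
    """

    observable: str
    bin_width: float
    table: pd.DataFrame
    values: np.ndarray


def binned_dynamics(
    ensemble, observable: str = "M", bin_width: float = 1.0, t_max: float | None = None
) -> BinnedDynamics:
    """Ensemble dynamics of a total count, summarised per time bin.

    Each trajectory contributes its time-weighted mean of the observable in
    every bin; the ensemble min, quartiles and median are then taken per bin.
    """
    if observable not in OBSERVABLES:
        raise ValueError(f"unknown observable {observable!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    items = _as_list(ensemble)
    horizon = t_max if t_max is not None else min(_horizon(it) for it in items)
    if any(_horizon(it) < horizon for it in items):
        raise ValueError("all trajectories must cover the analysis horizon")
    row = OBSERVABLES[observable]
    per_traj = []
    for item in items:
        if isinstance(item, Trajectory):
            means = K.binned_time_averages(*_traj_log(item), horizon, bin_width)[row]
        else:
            nbins = int(np.floor(horizon / bin_width))
            means = np.empty(nbins)
            for b in range(nbins):
                w = _count_weights(item, b * bin_width, (b + 1) * bin_width)[row]
                means[b] = np.average(np.arange(w.size), weights=w)
        per_traj.append(means)
    values = np.vstack(per_traj)
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0, method="linear")
    table = pd.DataFrame(
        {
            "time": np.arange(values.shape[1]) * bin_width,
            "min": q[0],
            "q25": q[1],
            "median": q[2],
            "q75": q[3],
            "max": q[4],
        }
    )
    return BinnedDynamics(observable, bin_width, table, values)


def establishment_time(
    binned: BinnedDynamics, level: float = 0.9, plateau_tail: float = 0.25
) -> tuple:
    """First time the median trace reaches ``level`` of its plateau.

    The plateau is the mean of the median trace over the final
    ``plateau_tail`` fraction of the horizon.  Returns ``(t, plateau)``;
    ``t`` is ``nan`` if the level is never reached.
    """
    med = binned.table["median"].to_numpy()
    times = binned.table["time"].to_numpy()
    tail = max(1, int(len(med) * plateau_tail))
    plateau = float(med[-tail:].mean())
    target = level * plateau
    hit = np.nonzero(med >= target)[0]
    t = float(times[hit[0]]) if hit.size else float("nan")
    return t, plateau


def relaxation_experiment(
    config: ModelConfig,
    reps: int,
    t_end: float,
    seed: int,
    observable: str = "M",
    method: str = "next_reaction",
) -> BinnedDynamics:
    """Decay (or persistence) of modification after the initiation signal stops.

    Starts from a fully methylated, fully transferase-occupied array with the
    initiation site shut (``k_on = 0``) and follows the total count of
    ``observable`` across ``reps`` replicates.
    """
    relaxed = config.with_rates(k_on=0.0)
    ens = iter_ensemble(relaxed, t_end, reps, seed, method=method, initial="all_M_occupied")
    return binned_dynamics(ens, observable=observable, t_max=t_end)


@dataclass
class SeedingResult:
    """Outcome of a seeding-bistability experiment.

    ``fraction`` of ``reps`` replicates ended in the high-methylation state
    (time-averaged total M over the final window above ``threshold``), with a
    95% Clopper–Pearson interval; ``high_state_mean_m`` is the ensemble mean
    of that time-averaged count over the high-state replicates.
    """

    k_seeds: int
    reps: int
    n_high: int
    fraction: float
    ci_low: float
    ci_high: float
    threshold: float
    high_state_mean_m: float
    final_mean_m: np.ndarray


def seeding_experiment(
    config: ModelConfig,
    k_seeds: int,
    reps: int,
    t_end: float,
    seed: int,
    threshold: float | None = None,
    final_fraction: float = 0.1,
    method: str = "next_reaction",
) -> SeedingResult:
    """Fraction of replicates that nucleate the high-methylation state.

    Each replicate starts from ``k_seeds`` equidistant methylated nucleosomes
    occupied by methyltransferases (the rest unmodified, no enzymes) and is
    classified by its time-averaged total methylation over the final
    ``final_fraction`` of the run: above ``threshold`` (default n/2) counts
    as high-state.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if threshold is None:
        threshold = config.n / 2
    finals = np.empty(reps)
    for i, traj in enumerate(
        iter_ensemble(config, t_end, reps, seed, method=method, initial=f"k_seeds({k_seeds})")
    ):
        t0 = t_end * (1.0 - final_fraction)
        integral = K.integrate_observables(*_traj_log(traj), t_end, t0, t_end)
        finals[i] = integral[OBSERVABLES["M"]] / (t_end - t0)
    high = finals > threshold
    n_high = int(high.sum())
    ci = stats.binomtest(n_high, reps).proportion_ci(confidence_level=0.95, method="exact")
    return SeedingResult(
        k_seeds=k_seeds,
        reps=reps,
        n_high=n_high,
        fraction=n_high / reps,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        threshold=float(threshold),
        high_state_mean_m=float(finals[high].mean()) if n_high else float("nan"),
        final_mean_m=finals,
    )


def boundary_statistic(
    ensemble,
    window: float = 10.0,
    window_starts: Sequence[float] = (0, 100, 200, 300, 400, 500, 600, 700),
) -> pd.DataFrame:
    """Replicate distribution of (total M − total A) in successive windows.

    For each window the per-replicate time average of the methylation minus
    acetylation count is computed (rounded to the nearest integer) and the
    distribution across replicates is returned as a tidy DataFrame with
    columns ``window_start``, ``delta``, ``probability``.
    """
    items = _as_list(ensemble)
    if len(items) < 2:
        raise ValueError("boundary statistic needs an ensemble of >= 2 replicates")
    if window <= 0:
        raise ValueError("window must be > 0")
    horizon = min(_horizon(it) for it in items)
    if max(window_starts) + window > horizon + 1e-9:
        raise ValueError("sampling window extends beyond the trajectory horizon")
    records = []
    deltas = np.empty((len(window_starts), len(items)))
    for j, item in enumerate(items):
        for w, t0 in enumerate(window_starts):
            if isinstance(item, Trajectory):
                integral = K.integrate_observables(*_traj_log(item), item.t_end, t0, t0 + window)
            else:
                wts = _count_weights(item, t0, t0 + window)
                integral = wts @ np.arange(wts.shape[1])
            deltas[w, j] = (integral[OBSERVABLES["M"]] - integral[OBSERVABLES["A"]]) / window
    for w, t0 in enumerate(window_starts):
        vals, counts = np.unique(np.rint(deltas[w]).astype(int), return_counts=True)
        for v, c in zip(vals, counts):
            records.append({"window_start": float(t0), "delta": int(v), "probability": c / len(items)})
    return pd.DataFrame.from_records(records)


def switching_summary(ensemble, majority_fraction: float = 0.5) -> pd.DataFrame:
    """Which replicates visit the majority-M and majority-A regions.

    A replicate visits the majority-M (majority-A) region when total M − total
    A exceeds ``majority_fraction * n`` (falls below the negative of it) at
    any point.  Returns one row per replicate with boolean columns
    ``visited_m``, ``visited_a``, ``switched`` (both).
    """
    items = _as_list(ensemble)
    rows = []
    for item in items:
        n = _n_sites(item)
        if isinstance(item, Trajectory):
            series = K.totals_series(item.initial.mods, item.initial.occ, *_traj_log(item)[3:])
            delta = series[:, OBSERVABLES["M"]] - series[:, OBSERVABLES["A"]]
        else:
            delta = (item.mods == 2).sum(axis=1) - (item.mods == 1).sum(axis=1)
        lim = majority_fraction * n
        visited_m = bool((delta > lim).any())
        visited_a = bool((delta < -lim).any())
        rows.append(
            {"visited_m": visited_m, "visited_a": visited_a, "switched": visited_m and visited_a}
        )
    return pd.DataFrame(rows)
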