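"""Configuration files, TSV serialisation and run manifests.

Configs are YAML mappings using the model's rate-constant symbols
(``k_on``, ``k_off``, ``k_transferase``, ...).  Event logs and kymographs are
TSV; a run manifest (JSON) records the config hash and every replicate seed
so any experiment can be re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .engine import KIND_NAMES, Kymograph, Trajectory, simulate
from .model import ArrayState, ConfigurationError, ModelConfig, RateSet
from .presets import get_preset

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "config_hash",
    "write_event_log",
    "read_event_log",
    "write_kymograph",
    "RunManifest",
    "write_outputs",
    "replay_manifest",
]

_RATE_KEYS = {f.name for f in dataclasses.fields(RateSet)}
_CONFIG_KEYS = {
    "n",
    "mechanism",
    "enzymes",
    "initiation_sites",
    "connectivity_sites",
    "rates",
    "initial_state",
    "preset",
}


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "n": config.n,
        "mechanism": config.mechanism,
        "enzymes": config.enzymes,
        "initiation_sites": dict(config.initiation_sites),
        "connectivity_sites": list(config.connectivity_sites),
        "rates": dataclasses.asdict(config.rates),
        "initial_state": config.initial_state
        if isinstance(config.initial_state, str)
        else "explicit",
    }


def _config_from_dict(data: dict) -> ModelConfig:
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    base: dict = {}
    if "preset" in data:
        base = config_to_dict(get_preset(data["preset"]).config)
        data = {k: v for k, v in data.items() if k != "preset"}
    merged = {**base, **{k: v for k, v in data.items() if k != "rates"}}
    rates = dict(base.get("rates", {}))
    rates.update(data.get("rates", {}))
    if rates:
        bad = set(rates) - _RATE_KEYS
        if bad:
            raise ConfigurationError(f"unknown rate keys: {sorted(bad)}")
        for k, v in rates.items():
            try:
                rates[k] = float(v)
            except (TypeError, ValueError):
                raise ConfigurationError(f"rate {k} is not a number: {v!r}") from None
        enzymes = merged.get("enzymes", "single_mt")
        merged["rates"] = RateSet.table1(enzymes, **rates)
    if "connectivity_sites" in merged:
        merged["connectivity_sites"] = tuple(merged["connectivity_sites"])
    return ModelConfig(**merged)


def load_config(path) -> ModelConfig:
    """Read and validate a YAML model configuration.

    Unknown keys, unknown rate symbols, malformed numbers, negative rates and
    out-of-range positions are rejected with descriptive errors.  A ``preset``
    key pulls in a bundled configuration which the remaining keys override;
    omitted rates take the reference defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    return _config_from_dict(data)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_hash(config: ModelConfig) -> str:
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# event logs and kymographs

_ENZ_NAME = {0: "", 1: "Mt", 2: "At"}
_ENZ_CODE = {"": 0, "Mt": 1, "At": 2}


def write_event_log(traj: Trajectory, path) -> None:
    """Event log TSV: time, kind, enzyme, pos1, pos2 (1-based positions).

    Header comments carry the metadata (seed, method, horizon, initial state)
    needed to reconstruct the trajectory exactly on read.
    """
    with open(path, "w") as fh:
        fh.write("# nucspread event log\n")
        fh.write(f"# seed={traj.seed} method={traj.method} t_end={traj.t_end!r}\n")
        fh.write(f"# initial_mods={''.join(map(str, traj.initial.mods))}\n")
        fh.write(f"# initial_occ={''.join(map(str, traj.initial.occ))}\n")
        fh.write("time\tkind\tenzyme\tpos1\tpos2\n")
        for i in range(traj.n_events):
            p2 = traj.pos2[i]
            fh.write(
                f"{float(traj.times[i])!r}\t{KIND_NAMES[traj.kinds[i]]}\t"
                f"{_ENZ_NAME[int(traj.enzymes[i])]}\t{traj.pos1[i] + 1}\t"
                f"{p2 + 1 if p2 >= 0 else ''}\n"
            )


def read_event_log(path, config: ModelConfig) -> Trajectory:
    """Reconstruct a :class:`Trajectory` written by :func:`write_event_log`."""
    kind_code = {k: i for i, k in enumerate(KIND_NAMES)}
    meta: dict = {}
    times, kinds, enzymes, pos1, pos2 = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            if line.startswith("time\t") or not line:
                continue
            t, kind, enz, p1, p2 = line.split("\t")
            times.append(float(t))
            kinds.append(kind_code[kind])
            enzymes.append(_ENZ_CODE[enz])
            pos1.append(int(p1) - 1)
            pos2.append(int(p2) - 1 if p2 else -1)
    initial = ArrayState(
        np.array([int(c) for c in meta["initial_mods"]], dtype=np.int8),
        np.array([int(c) for c in meta["initial_occ"]], dtype=np.int8),
    )
    return Trajectory(
        config=config,
        seed=int(meta["seed"]),
        method=meta["method"],
        t_end=float(meta["t_end"]),
        initial=initial,
        times=np.array(times, dtype=np.float64),
        kinds=np.array(kinds, dtype=np.int8),
        enzymes=np.array(enzymes, dtype=np.int8),
        pos1=np.array(pos1, dtype=np.int16),
        pos2=np.array(pos2, dtype=np.int16),
    )


def write_kymograph(kymo: Kymograph, path) -> None:
    """Kymograph TSV: per sample time, integer-coded state of each position.

    Columns ``m<i>`` hold modification codes (U=0, A=1, M=2) and ``o<i>``
    occupancy codes (empty=0, Mt=1, At=2) for 1-based position i.
    """
    n = kymo.mods.shape[1]
    with open(path, "w") as fh:
        fh.write("# nucspread kymograph; mods U/A/M=0/1/2, occ empty/Mt/At=0/1/2\n")
        header = ["time"] + [f"m{i+1}" for i in range(n)] + [f"o{i+1}" for i in range(n)]
        fh.write("\t".join(header) + "\n")
        for r in range(kymo.mods.shape[0]):
            row = [repr(float(kymo.times[r]))]
            row += [str(int(v)) for v in kymo.mods[r]]
            row += [str(int(v)) for v in kymo.occ[r]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# manifests


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    config_hash: str
    master_seed: int
    replicate_seeds: list
    method: str
    t_end: float
    version: str
    wall_time_s: float
    outputs: list

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_outputs(
    trajectories,
    summaries: dict,
    out_dir,
    master_seed: int = 0,
    kymograph_dt: float | None = None,
) -> RunManifest:
    """Write event logs, optional kymographs, summary tables and a manifest.

    ``summaries`` maps table name -> DataFrame (written as ``<name>.tsv``).
    Returns the :class:`RunManifest`, also written as ``manifest.json``.
    """
    from . import __version__

    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trajectories = list(trajectories)
    outputs = []
    config = trajectories[0].config if trajectories else None
    if config is not None:
        save_config(config, out / "config.yaml")
        outputs.append("config.yaml")
    for i, traj in enumerate(trajectories):
        name = f"events_{i:03d}.tsv"
        write_event_log(traj, out / name)
        outputs.append(name)
        if kymograph_dt is not None:
            kname = f"kymograph_{i:03d}.tsv"
            write_kymograph(traj.snapshot_matrix(kymograph_dt), out / kname)
            outputs.append(kname)
    for name, table in summaries.items():
        fname = f"{name}.tsv"
        table.to_csv(out / fname, sep="\t", index=True)
        outputs.append(fname)
    manifest = RunManifest(
        config_hash=config_hash(config) if config is not None else "",
        master_seed=int(master_seed),
        replicate_seeds=[int(t.seed) for t in trajectories],
        method=trajectories[0].method if trajectories else "next_reaction",
        t_end=float(trajectories[0].t_end) if trajectories else 0.0,
        version=__version__,
        wall_time_s=time.perf_counter() - t0,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest


def replay_manifest(out_dir) -> list:
    """Re-simulate every replicate recorded in ``out_dir``'s manifest."""
    out = Path(out_dir)
    manifest = RunManifest.read(out / "manifest.json")
    config = load_config(out / "config.yaml")
    return [
        simulate(config, manifest.t_end, seed, method=manifest.method)
        for seed in manifest.replicate_seeds
    ]
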