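"""Readers and writers: SBML models, YAML configs, expression tables,
time-series CSV, position snapshots, and the per-run log.

CSV files are comma-separated UTF-8 with '.' decimals regardless of locale;
floats are written at full precision so read → write → read is lossless.
"""
from __future__ import annotations

import dataclasses
import os
from typing import Optional

import cobra
import pandas as pd
import yaml

from .core_types import CellSpec, FeedEvent, MetaboliteSpec, SimulationConfig
from .metabolism import MetabolicModelHandle


class ModelLoadError(RuntimeError):
    """Problems loading or interpreting a metabolic model file."""


# ---------------------------------------------------------------------------
# SBML models
# ---------------------------------------------------------------------------

def read_model(path: str, biomass_reaction: Optional[str] = None) -> MetabolicModelHandle:
    """Load an SBML (L3/FBC) model and identify its biomass objective.

    Without an explicit ``biomass_reaction`` override the model's declared
    objective is used; zero or multiple candidate objective reactions raise
    a :class:`ModelLoadError` naming the problem. Exchange reactions
    (single-metabolite boundary reactions) are auto-detected and mapped by
    their metabolite's SBML id; simulation configs override this map with
    their own metabolite naming.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        model = cobra.io.read_sbml_model(path)
    except Exception as exc:
        raise ModelLoadError(f"cannot parse SBML model {path}: {exc}") from exc
    if biomass_reaction is None:
        coeffs = cobra.util.solver.linear_reaction_coefficients(model)
        candidates = [r.id for r in coeffs]
        if len(candidates) == 0:
            raise ModelLoadError(
                f"{path}: no objective reaction declared and no override given"
            )
        if len(candidates) > 1:
            raise ModelLoadError(
                f"{path}: {len(candidates)} candidate biomass reactions "
                f"({', '.join(candidates)}) and no override given"
            )
        biomass_reaction = candidates[0]
    exchange_map = {}
    for rxn in model.boundary:
        if len(rxn.metabolites) == 1 and rxn.id != biomass_reaction:
            met = next(iter(rxn.metabolites))
            exchange_map[met.id] = rxn.id
    return MetabolicModelHandle(
        model=model, biomass_reaction_id=biomass_reaction, exchange_map=exchange_map
    )


def write_model(handle: MetabolicModelHandle, path: str) -> None:
    cobra.io.write_sbml_model(handle.model, path)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(path: str) -> dict[str, float]:
    """Two-column tab-separated gene → level table; header row optional."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"expression table not found: {path}")
    table: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected two tab-separated columns")
            try:
                level = float(parts[1])
            except ValueError:
                if i == 0:
                    continue  # header
                raise ValueError(f"{path}:{i + 1}: non-numeric expression level")
            table[parts[0]] = level
    return table


def write_expression(table: dict[str, float], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tlevel\n")
        for gene, level in table.items():
            fh.write(f"{gene}\t{level!r}\n")


# ---------------------------------------------------------------------------
# Time series (long-format CSV)
# ---------------------------------------------------------------------------

def write_timeseries(ts: pd.DataFrame, path: str) -> None:
    """Write a wide time-series frame as long CSV (time_min, variable, value)."""
    if ts.empty:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("time_min,variable,value\n")
        return
    long = ts.melt(id_vars=["time_min"], var_name="variable", value_name="value")
    long.to_csv(path, index=False)


def read_timeseries(path: str) -> pd.DataFrame:
    """Read a long-format CSV back into the wide layout (lossless)."""
    long = pd.read_csv(path)
    if long.empty:
        return pd.DataFrame(columns=["time_min"])
    order = list(dict.fromkeys(long["variable"]))
    wide = long.pivot(index="time_min", columns="variable", values="value")
    wide = wide[order].reset_index()
    wide.columns.name = None
    return wide.sort_values("time_min").reset_index(drop=True)


def write_positions_snapshot(records: pd.DataFrame, path: str) -> None:
    """Positions CSV with columns t, id, type, x, y, z."""
    records.to_csv(path, index=False)


def snapshot_positions(env, time_min: float) -> pd.DataFrame:
    rows = []
    for a in env.live_agents():
        rows.append((time_min, a.id, a.species, *map(float, a.position)))
    store = env.packages
    for i in range(store.size):
        if store.alive[i]:
            rows.append(
                (time_min, i, f"pkg:{store.met_ids[store.met[i]]}",
                 *map(float, store.positions[i]))
            )
    return pd.DataFrame(rows, columns=["t", "id", "type", "x", "y", "z"])


# ---------------------------------------------------------------------------
# Configuration files (YAML)
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "environment": {
            "dims_um": list(config.env_dims_um),
            "boundary": config.boundary,
        },
        "simulation": {
            "dt_min": config.dt_min,
            "t_end_min": config.t_end_min,
            "seed": config.seed,
            "speed_um_per_h": config.speed_um_per_h,
            "package_size": config.package_size,
            "colony_size": config.colony_size,
            "max_retries": config.max_retries,
            "record_every": config.record_every,
        },
        "species": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(s).items() if v is not None}
            for s in config.species
        ],
        "metabolites": [
            {k: v for k, v in dataclasses.asdict(m).items() if v not in (None, {})}
            for m in config.metabolites
        ],
        "feeding": [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(f).items() if v is not None}
            for f in config.feeding
        ],
    }


def save_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path: str) -> SimulationConfig:
    """Parse a YAML config file; raises on unreadable files.

    Parsing errors are distinct from validation failures: call
    :func:`acbm.core_types.validate_config` on the result to check the
    invariants.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: not a mapping")
    env = raw.get("environment", {})
    sim = raw.get("simulation", {})
    species = [CellSpec(**{**s, "substrates": tuple(s.get("substrates", ()))})
               for s in raw.get("species", [])]
    mets = [MetaboliteSpec(**m) for m in raw.get("metabolites", [])]
    feeds = []
    for f in raw.get("feeding", []):
        f = dict(f)
        if f.get("point_um") is not None:
            f["point_um"] = tuple(f["point_um"])
        feeds.append(FeedEvent(**f))
    return SimulationConfig(
        env_dims_um=tuple(env.get("dims_um", (1000.0, 400.0, 400.0))),
        boundary=env.get("boundary", "reflective"),
        dt_min=sim.get("dt_min", 1.0),
        t_end_min=sim.get("t_end_min", 60.0),
        seed=sim.get("seed", 0),
        speed_um_per_h=sim.get("speed_um_per_h", 8000.0),
        package_size=sim.get("package_size", 5e5),
        colony_size=sim.get("colony_size", 1000),
        max_retries=sim.get("max_retries", 10),
        record_every=sim.get("record_every", 1),
        species=species,
        metabolites=mets,
        feeding=feeds,
    )


def write_run_log(path: str, config: SimulationConfig, termination: str) -> None:
    """Per-run log: config echo, seed, solver, termination reason."""
    import cobra as _cobra

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# acbm run log\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"solver: {_cobra.Configuration().solver.__name__}\n")
        fh.write(f"termination: {termination}\n")
        fh.write("config:\n")
        fh.write(yaml.safe_dump(config_to_dict(config), sort_keys=False))
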