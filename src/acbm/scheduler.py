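"""Simulation orchestration: the environment, the time loop, and replicates.

A run initialises the cube, places colony agents and metabolite packages
uniformly at random, then loops: apply due feed events, move every package,
step every agent (in a freshly shuffled order), and record one time-series
row. The loop ends at the configured horizon or when the population is
extinct, whichever comes first; the final state is always recorded.

Two invariants are asserted after every step when ``check_invariants`` is
on (the default): occupancy exclusivity (mesh bookkeeping matches the
agents' claimed elements exactly) and metabolite conservation (packages +
sub-package accumulators + dust = initial + fed + produced − consumed).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_types import (
    AVOGADRO,
    PG_TO_G,
    CellAgent,
    FeedEvent,
    SimulationConfig,
    initial_counts,
    molecules_from_concentration,
    validate_config,
)
from .lifecycle import step_cell
from .metabolism import MetabolicModelHandle, apply_expression_bounds
from .spatial import (
    OccupancyGrid,
    PackageStore,
    occupied_elements,
    random_direction,
    uniform_positions,
)


class ConfigError(ValueError):
    """Raised when a run is attempted with an invalid configuration."""


@dataclass
class ReplicateSet:
    runs: list["SimResult"]
    sd: pd.DataFrame
    max_sd: float


@dataclass
class SimResult:
    timeseries: pd.DataFrame
    termination: str
    agent_events: Optional[pd.DataFrame] = None


@dataclass
class _Ledger:
    initial: float = 0.0
    fed: float = 0.0
    consumed: float = 0.0
    produced: float = 0.0
    dust: float = 0.0


class Environment:
    """Mutable world state: mesh, agents, packages, and bookkeeping ledgers."""

    _CAP = 1024

    def __init__(
        self,
        config: SimulationConfig,
        models: dict[str, MetabolicModelHandle],
        rng: np.random.Generator,
    ):
        self.config = config
        self.rng = rng
        self.grid = OccupancyGrid(config.env_dims_um)
        self.specs = {s.name: s for s in config.species}
        self.handles: dict[str, MetabolicModelHandle] = {}
        for s in config.species:
            handle = models[s.name]
            if s.uptake_mode == "expression":
                from .io_formats import read_expression

                handle = apply_expression_bounds(
                    handle, read_expression(s.expression_path), s.expression_scale
                )
            # the config's metabolite naming is the source of truth
            rxn_ids = {r.id for r in handle.model.reactions}
            mapping = {
                m.id: m.exchange_for(s.name)
                for m in config.metabolites
                if m.exchange_for(s.name) in rxn_ids
            }
            handle.set_exchange_map(mapping)
            for sub in s.substrates:
                if config.metabolite(sub).is_substrate and sub not in mapping:
                    raise ConfigError(
                        f"species {s.name}: substrate '{sub}' has no exchange "
                        f"reaction in its model"
                    )
            self.handles[s.name] = handle
        self.packages = PackageStore(
            [m.id for m in config.metabolites],
            periodic_dims=config.env_dims_um if config.boundary == "periodic" else None,
        )
        self.substrates_of = {
            s.name: [m for m in s.substrates if config.metabolite(m).is_substrate]
            for s in config.species
        }
        self.substrate_codes = {
            name: frozenset(self.packages.met_code[m] for m in mets)
            for name, mets in self.substrates_of.items()
        }
        self.agents: dict[int, CellAgent] = {}
        self._next_id = 0
        self._pos = np.zeros((self._CAP, 3))
        self._mass = np.zeros(self._CAP)
        self._alive = np.zeros(self._CAP, dtype=bool)
        self._row: dict[int, int] = {}
        self._nrows = 0
        self.ledgers = {m.id: _Ledger() for m in config.metabolites}
        self.dead_biomass_pg = 0.0
        self.time_min = 0.0
        self._pending_feeds = sorted(config.feeding, key=lambda f: f.time_min)

    # -- agent registry -----------------------------------------------------
    def next_agent_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def register_agent(self, agent: CellAgent) -> None:
        self.agents[agent.id] = agent
        if self._nrows >= len(self._mass):
            grow = len(self._mass) * 2
            self._pos = np.resize(self._pos, (grow, 3))
            self._mass = np.resize(self._mass, grow)
            alive = np.zeros(grow, dtype=bool)
            alive[: self._nrows] = self._alive[: self._nrows]
            self._alive = alive
        r = self._nrows
        self._nrows += 1
        self._row[agent.id] = r
        self._pos[r] = agent.position
        self._mass[r] = agent.biomass_pg
        self._alive[r] = True

    def sync_agent(self, agent: CellAgent) -> None:
        r = self._row[agent.id]
        self._pos[r] = agent.position
        self._mass[r] = agent.biomass_pg
        self._alive[r] = agent.alive

    def kill(self, agent: CellAgent) -> None:
        if not agent.alive:
            return
        self.grid.release(agent.occupied, agent.id)
        agent.occupied = frozenset()
        agent.alive = False
        self._alive[self._row[agent.id]] = False
        self.dead_biomass_pg += agent.biomass_pg
        for met, acc in agent.accumulators.items():
            if acc >= 1.0:
                self.packages.add(met, agent.position.copy(), acc)
            elif acc > 0:
                self.ledgers[met].dust += acc
        agent.accumulators = {}

    def live_agents(self) -> list[CellAgent]:
        return [a for a in self.agents.values() if a.alive]

    def agent_masses_within(self, center: np.ndarray, radius: float) -> np.ndarray:
        """Biomass (pg) of all live agents within ``radius`` of ``center``."""
        pos = self._pos[: self._nrows]
        live = self._alive[: self._nrows]
        delta = np.abs(pos - center)
        if self.config.boundary == "periodic":
            dims = np.asarray(self.config.env_dims_um)
            delta = np.minimum(delta, dims - delta)
        d2 = (delta**2).sum(axis=1)
        sel = live & (d2 <= radius * radius)
        return self._mass[: self._nrows][sel]

    # -- ledgers ------------------------------------------------------------
    def record_consumed(self, met: str, molecules: float) -> None:
        self.ledgers[met].consumed += molecules

    def record_produced(self, met: str, molecules: float) -> None:
        self.ledgers[met].produced += molecules

    # -- setup --------------------------------------------------------------
    def initialize(self) -> None:
        cfg = self.config
        agents_n, packages_n = initial_counts(cfg)
        dims = np.asarray(cfg.env_dims_um)
        for s in cfg.species:
            unit = cfg.colony_size * s.mass_pg
            for _ in range(agents_n[s.name]):
                placed = False
                for _ in range(10000):
                    pos = uniform_positions(self.rng, 1, dims)[0]
                    direction = random_direction(self.rng)
                    els = occupied_elements(pos, s, direction)
                    if all(self.grid.in_bounds(e) for e in els) and all(
                        self.grid.is_free(e) for e in els
                    ):
                        agent = CellAgent(
                            id=self.next_agent_id(),
                            species=s.name,
                            position=pos,
                            biomass_pg=unit,
                            direction=direction,
                        )
                        agent.occupied = els
                        self.grid.claim(els, agent.id)
                        self.register_agent(agent)
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        f"could not place agent of species {s.name}: environment full"
                    )
        for m in cfg.metabolites:
            k = packages_n[m.id]
            if k > 0:
                pos = uniform_positions(self.rng, k, dims)
                self.packages.add_many(m.id, pos, cfg.package_size)
            self.ledgers[m.id].initial = k * cfg.package_size

    # -- feeding ------------------------------------------------------------
    def apply_feed(self, event: FeedEvent) -> int:
        """Add feed packages; returns the number of packages created."""
        cfg = self.config
        molecules = molecules_from_concentration(
            event.amount_g_per_l, cfg.metabolite(event.metabolite).mw_g_per_mol, cfg.volume_l
        )
        k = int(molecules // cfg.package_size)
        remainder = molecules - k * cfg.package_size
        if event.mode == "point":
            pos = np.tile(np.asarray(event.point_um, dtype=float), (k, 1))
        else:
            pos = uniform_positions(self.rng, k, np.asarray(cfg.env_dims_um))
        self.packages.add_many(event.metabolite, pos, cfg.package_size)
        created = k
        if remainder >= 1.0:
            if event.mode == "point":
                p = np.asarray(event.point_um, dtype=float)
            else:
                p = uniform_positions(self.rng, 1, np.asarray(cfg.env_dims_um))[0]
            self.packages.add(event.metabolite, p, remainder)
            created += 1
            remainder = 0.0
        self.ledgers[event.metabolite].fed += molecules - remainder
        return created

    # -- invariants ---------------------------------------------------------
    def check_invariants(self) -> None:
        claimed = 0
        for a in self.live_agents():
            claimed += len(a.occupied)
            for el in a.occupied:
                owner = self.grid.owner(el)
                if owner != a.id:
                    raise AssertionError(
                        f"element {el} of agent {a.id} owned by {owner}"
                    )
        if claimed != self.grid.occupied_count():
            raise AssertionError(
                f"occupancy leak: {claimed} claimed vs {self.grid.occupied_count()} in mesh"
            )
        dims = np.asarray(self.config.env_dims_um)
        pos = self.packages.positions[: self.packages.size][
            self.packages.alive[: self.packages.size]
        ]
        if len(pos) and ((pos < -1e-9).any() or (pos > dims + 1e-9).any()):
            raise AssertionError("package outside environment")
        for a in self.live_agents():
            if (a.position < -1e-9).any() or (a.position > dims + 1e-9).any():
                raise AssertionError(f"agent {a.id} outside environment")
        for met, led in self.ledgers.items():
            have = self.packages.total_molecules(met) + led.dust
            for a in self.live_agents():
                have += a.accumulators.get(met, 0.0)
            expect = led.initial + led.fed + led.produced - led.consumed
            tol = 1e-6 * max(1.0, abs(expect))
            if abs(have - expect) > tol:
                raise AssertionError(
                    f"{met} not conserved: have {have:.6g}, expect {expect:.6g}"
                )

    # -- reporting ----------------------------------------------------------
    def stats_row(self, starved: Optional[float], mus: list[float]) -> dict:
        cfg = self.config
        vol = cfg.volume_l
        row: dict[str, float] = {"time_min": self.time_min}
        for s in cfg.species:
            live = [a for a in self.live_agents() if a.species == s.name]
            row[f"biomass_{s.name}_g_per_l"] = (
                sum(a.biomass_pg for a in live) * PG_TO_G / vol
            )
            row[f"agents_{s.name}"] = float(len(live))
        for m in cfg.metabolites:
            n = self.packages.total_molecules(m.id) + sum(
                a.accumulators.get(m.id, 0.0) for a in self.live_agents()
            )
            row[f"conc_{m.id}_g_per_l"] = n * m.mw_g_per_mol / (AVOGADRO * vol)
        row["starved_fraction"] = float("nan") if starved is None else starved
        arr = np.asarray(mus, dtype=float)
        row["mu_mean"] = float(arr.mean()) if len(arr) else float("nan")
        row["mu_min"] = float(arr.min()) if len(arr) else float("nan")
        row["mu_max"] = float(arr.max()) if len(arr) else float("nan")
        return row


def run(
    config: SimulationConfig,
    models: Optional[dict[str, MetabolicModelHandle]] = None,
    check_invariants: bool = True,
    record_agent_events: bool = False,
) -> SimResult:
    """Run one simulation and return its time series.

    ``models`` maps species names to pre-built model handles; when omitted,
    models are loaded from each species' ``model_path``. A fixed config seed
    yields a bit-identical time series on repeat runs.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid configuration:\n" + "\n".join(violations))
    if models is None:
        from .io_formats import read_model

        models = {}
        for s in config.species:
            if not s.model_path:
                raise ConfigError(f"species {s.name}: no model handle and no model_path")
            models[s.name] = read_model(s.model_path)

    rng = np.random.default_rng(config.seed)
    env = Environment(config, models, rng)
    env.initialize()
    if check_invariants:
        env.check_invariants()

    rows = [env.stats_row(starved=None, mus=[])]
    events: list[tuple] = []
    step_i = 0
    termination = "t_end"
    while env.time_min < config.t_end_min - 1e-9:
        if not any(a.alive for a in env.agents.values()):
            termination = "all_dead"
            break
        while env._pending_feeds and env._pending_feeds[0].time_min <= env.time_min + 1e-9:
            env.apply_feed(env._pending_feeds.pop(0))
        env.packages.move_all(
            rng, config.speed_um_per_h, config.dt_min, config.env_dims_um, config.boundary
        )
        env.packages.build_index()
        ids = sorted(a.id for a in env.agents.values() if a.alive)
        order = rng.permutation(len(ids))
        mus: list[float] = []
        n_started = len(ids)
        n_starved = 0
        for j in order:
            agent = env.agents[ids[j]]
            ev = step_cell(agent, env, rng)
            env.sync_agent(agent)
            if ev.ate:
                mus.append(ev.mu)
            else:
                n_starved += 1
            if record_agent_events:
                events.append(
                    (env.time_min + config.dt_min, agent.id, agent.species, ev.ate, ev.died)
                )
        if env.packages.live_count() < 0.75 * env.packages.size:
            env.packages.compact()
        env.time_min += config.dt_min
        step_i += 1
        if check_invariants:
            env.check_invariants()
        starved = n_starved / n_started if n_started else float("nan")
        last_step = env.time_min >= config.t_end_min - 1e-9 or not any(
            a.alive for a in env.agents.values()
        )
        if step_i % config.record_every == 0 or last_step:
            rows.append(env.stats_row(starved=starved, mus=mus))

    if termination == "t_end" and not any(a.alive for a in env.agents.values()):
        termination = "all_dead"
    ts = pd.DataFrame(rows)
    ev_df = (
        pd.DataFrame(events, columns=["time_min", "agent_id", "species", "ate", "died"])
        if record_agent_events
        else None
    )
    result = SimResult(timeseries=ts, termination=termination, agent_events=ev_df)
    result.env = env  # final state, for inspection
    return result


def replicate_seeds(base_seed: int, k: int) -> list[int]:
    return [(base_seed + 1000003 * i) % (2**31) for i in range(k)]


def run_replicates(
    config: SimulationConfig,
    k: int,
    models: Optional[dict[str, MetabolicModelHandle]] = None,
    base_seed: Optional[int] = None,
    **kwargs,
) -> ReplicateSet:
    """Run ``k`` independent replicates and the per-variable SD over them.

    Seeds derive deterministically from ``base_seed`` (default: the config
    seed). The SD table is computed per time point per variable over the
    time range common to all replicates; ``max_sd`` is the largest SD over
    the biomass and concentration columns, the run-to-run variability
    measure for stochastic movement.
    """
    if k < 2:
        raise ValueError("need at least 2 replicates")
    base = config.seed if base_seed is None else base_seed
    runs = []
    for seed in replicate_seeds(base, k):
        cfg = dataclasses.replace(config, seed=seed)
        runs.append(run(cfg, models=models, **kwargs))
    n = min(len(r.timeseries) for r in runs)
    frames = [r.timeseries.iloc[:n].reset_index(drop=True) for r in runs]
    stack = np.stack([f.to_numpy(dtype=float) for f in frames])
    sd = pd.DataFrame(
        np.std(stack, axis=0, ddof=1), columns=frames[0].columns
    )
    sd["time_min"] = frames[0]["time_min"]
    value_cols = [
        c for c in sd.columns if c.startswith("biomass_") or c.startswith("conc_")
    ]
    max_sd = float(sd[value_cols].to_numpy().max()) if value_cols else float("nan")
    return ReplicateSet(runs=runs, sd=sd, max_sd=max_sd)
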