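"""Per-agent step process: search, eat, divide, starve, die."""
import numpy as np
import pytest

from acbm.core_types import (
    CellAgent,
    CellSpec,
    MetaboliteSpec,
    SimulationConfig,
)
from acbm.fixtures import toy_model
from acbm.lifecycle import check_death, check_division, is_starved, step_cell
from acbm.scheduler import Environment
from acbm.spatial import occupied_elements


def tiny_env(seed=0, survive=30.0, colony=1):
    spec = CellSpec(
        name="bug",
        radius_um=0.4,
        mass_pg=0.28,
        search_radius_um=15.0,
        eat_radius_um=5.0,
        survive_time_min=survive,
        substrates=("glc",),
        max_uptake={"EX_glc": 10.0},
    )
    cfg = SimulationConfig(
        env_dims_um=(50.0, 50.0, 50.0),
        dt_min=1.0,
        t_end_min=60.0,
        species=[spec],
        metabolites=[
            MetaboliteSpec("glc", "EX_glc", 180.16, 0.0, is_substrate=True),
            MetaboliteSpec("ac", "EX_ac", 60.05, 0.0, is_substrate=False),
        ],
        package_size=1e9,
        colony_size=colony,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    env = Environment(cfg, {"bug": toy_model()}, rng)
    return env, rng


def add_agent(env, position, biomass_pg=None, hunger=0.0):
    spec = env.specs["bug"]
    agent = CellAgent(
        id=env.next_agent_id(),
        species="bug",
        position=np.asarray(position, dtype=float),
        biomass_pg=biomass_pg
        if biomass_pg is not None
        else env.config.colony_size * spec.mass_pg,
        direction=np.array([1.0, 0.0, 0.0]),
        hunger_clock_min=hunger,
    )
    els = occupied_elements(agent.position, spec, agent.direction)
    agent.occupied = els
    env.grid.claim(els, agent.id)
    env.register_agent(agent)
    return agent


def add_package(env, position, n=1e9, met="glc"):
    i = env.packages.add(met, np.asarray(position, dtype=float), n)
    env.ledgers[met].initial += n
    return i


class TestStepCell:
    def test_no_packages_advances_hunger_and_moves(self):
        env, rng = tiny_env()
        agent = add_agent(env, [25.0, 25.0, 25.0])
        env.packages.build_index()
        ev = step_cell(agent, env, rng)
        assert not ev.ate and not ev.died
        assert agent.hunger_clock_min == 1.0
        assert is_starved(agent)

    def test_package_in_reach_is_eaten_and_debited(self):
        env, rng = tiny_env()
        agent = add_agent(env, [25.0, 25.0, 25.0], hunger=10.0)
        pkg = add_package(env, [27.0, 25.0, 25.0])
        env.packages.build_index()
        ev = step_cell(agent, env, rng)
        assert ev.ate and ev.mu > 0
        assert agent.hunger_clock_min == 0.0
        assert env.packages.n[pkg] < 1e9  # molecules debited
        assert env.ledgers["glc"].consumed > 0
        assert not is_starved(agent)

    def test_hungry_at_entry_dies_without_acting(self):
        env, rng = tiny_env(survive=30.0)
        agent = add_agent(env, [25.0, 25.0, 25.0], hunger=30.0)
        add_package(env, [26.0, 25.0, 25.0])
        env.packages.build_index()
        pos = agent.position.copy()
        ev = step_cell(agent, env, rng)
        assert ev.died and not ev.ate
        assert not agent.alive
        assert np.all(agent.position == pos)
        assert env.packages.n[0] == 1e9  # untouched

    def test_death_releases_mesh_elements(self):
        env, rng = tiny_env(survive=1.0)
        agent = add_agent(env, [25.0, 25.0, 25.0], hunger=5.0)
        env.packages.build_index()
        step_cell(agent, env, rng)
        assert env.grid.occupied_count() == 0

    def test_secretion_accumulates_toward_packages(self):
        env, rng = tiny_env(colony=1)
        agent = add_agent(env, [25.0, 25.0, 25.0])
        add_package(env, [26.0, 25.0, 25.0])
        env.packages.build_index()
        step_cell(agent, env, rng)
        # acetate secreted but far below one package: lives in the accumulator
        assert 0 < agent.accumulators["ac"] < env.config.package_size
        assert env.ledgers["ac"].produced == pytest.approx(agent.accumulators["ac"])


class TestCheckDeath:
    def test_fresh_agent_survives(self):
        env, _ = tiny_env()
        agent = add_agent(env, [25.0, 25.0, 25.0])
        assert not check_death(agent, env.specs["bug"])

    def test_clock_at_survive_time_dies(self):
        env, _ = tiny_env(survive=7.0)
        agent = add_agent(env, [25.0, 25.0, 25.0], hunger=7.0)
        assert check_death(agent, env.specs["bug"])


class TestDivision:
    def threshold(self, env):
        return 2.0 * env.config.colony_size * env.specs["bug"].mass_pg

    def test_below_threshold_no_daughter(self):
        env, rng = tiny_env()
        agent = add_agent(env, [25.0, 25.0, 25.0], biomass_pg=1.9 * 0.28)
        assert check_division(agent, env.specs["bug"], env, rng) is None

    def test_at_threshold_biomass_is_conserved(self):
        env, rng = tiny_env()
        total = self.threshold(env)
        agent = add_agent(env, [25.0, 25.0, 25.0], biomass_pg=total)
        daughter = check_division(agent, env.specs["bug"], env, rng)
        assert daughter is not None
        assert agent.biomass_pg + daughter.biomass_pg == pytest.approx(total)
        assert agent.occupied.isdisjoint(daughter.occupied)
        assert daughter.id in env.agents

    def test_fully_crowded_defers_division(self):
        env, rng = tiny_env()
        agent = add_agent(env, [25.5, 25.5, 25.5], biomass_pg=self.threshold(env))
        blocker = 999
        home = (25, 25, 25)
        r = int(np.ceil(5 * 2 * env.specs["bug"].radius_um)) + 1
        for i in range(home[0] - r, home[0] + r + 1):
            for j in range(home[1] - r, home[1] + r + 1):
                for k in range(home[2] - r, home[2] + r + 1):
                    if (i, j, k) != home:
                        env.grid.claim([(i, j, k)], blocker)
        assert check_division(agent, env.specs["bug"], env, rng) is None
        assert agent.biomass_pg == pytest.approx(self.threshold(env))
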