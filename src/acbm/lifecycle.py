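"""Per-agent time-step process: search → move → eat → metabolize → divide/die.

Each step an agent looks for the nearest consumable package within its
search radius. Finding none, it moves randomly and its hunger clock
advances; otherwise it moves toward the package at its normal speed, eats
every substrate package inside its eating radius, and the growth LP decides
how much of the intake is actually metabolised (the excess stays where it
was found). Division and death checks run last. An agent whose hunger clock
has reached its survive time dies before doing anything else, so no agent
ever eats and dies in the same step.

Agents are updated in an order freshly randomised every step, which avoids a
systematic first-mover advantage in substrate contention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_types import AVOGADRO, PG_TO_G, CellAgent, CellSpec
from .metabolism import (
    delta_concentration,
    local_biomass_concentration,
    michaelis_menten_bound,
    solve_growth,
    update_biomass,
    uptake_bound_from_intake,
)
from .spatial import directed_move, occupied_elements, positions_in_sphere, try_move


@dataclass
class StepEvents:
    ate: bool = False
    divided: bool = False
    died: bool = False
    mu: float = 0.0


def check_death(agent: CellAgent, spec: CellSpec) -> bool:
    """True iff the agent has gone hungry for at least its survive time."""
    return agent.hunger_clock_min >= spec.survive_time_min


def is_starved(agent: CellAgent) -> bool:
    """True iff the agent failed to eat in its most recent step."""
    return not agent.ate_last_step


def check_division(agent: CellAgent, spec: CellSpec, env, rng) -> Optional[CellAgent]:
    """Split the colony once its biomass reaches twice the colony unit mass.

    The daughter is placed on the nearest free element set, searching
    outward from the mother (ties broken by lowest flat element index) up to
    five cell diameters; if no space is found the division is deferred and
    the mother keeps its biomass.
    """
    threshold = 2.0 * env.config.colony_size * spec.mass_pg
    if agent.biomass_pg < threshold:
        return None
    grid = env.grid
    diameter = 2.0 * spec.radius_um if spec.shape == "cocci" else (spec.length_um or 2.0 * spec.radius_um)
    max_r = int(np.ceil(5.0 * diameter))
    home = grid.containing_element(agent.position)
    nx, ny, nz = grid.shape
    daughter_dir = np.asarray(agent.direction, dtype=float)

    candidates: list[tuple[float, int, tuple[int, int, int]]] = []
    for ring in range(1, max_r + 1):
        candidates.clear()
        for di in range(-ring, ring + 1):
            for dj in range(-ring, ring + 1):
                for dk in range(-ring, ring + 1):
                    if max(abs(di), abs(dj), abs(dk)) != ring:
                        continue
                    el = (home[0] + di, home[1] + dj, home[2] + dk)
                    if not grid.in_bounds(el):
                        continue
                    center = grid.element_center(el)
                    d2 = float(((center - agent.position) ** 2).sum())
                    flat = (el[0] * ny + el[1]) * nz + el[2]
                    candidates.append((d2, flat, el))
        for _, _, el in sorted(candidates):
            center = grid.element_center(el)
            els = occupied_elements(center, spec, daughter_dir)
            if all(grid.in_bounds(e) for e in els) and all(grid.is_free(e) for e in els):
                half = agent.biomass_pg / 2.0
                agent.biomass_pg = half
                daughter = CellAgent(
                    id=env.next_agent_id(),
                    species=agent.species,
                    position=center,
                    biomass_pg=half,
                    direction=daughter_dir.copy(),
                    hunger_clock_min=agent.hunger_clock_min,
                )
                daughter.occupied = els
                grid.claim(els, daughter.id)
                env.register_agent(daughter)
                return daughter
    return None  # fully crowded: defer to the next step


def step_cell(agent: CellAgent, env, rng: np.random.Generator) -> StepEvents:
    """Run one time step of the cell process for a single agent."""
    spec = env.specs[agent.species]
    ev = StepEvents()
    if check_death(agent, spec):
        env.kill(agent)
        ev.died = True
        agent.ate_last_step = False
        return ev

    cfg = env.config
    dt = cfg.dt_min
    dt_h = dt / 60.0
    speed = spec.speed_um_per_h if spec.speed_um_per_h is not None else cfg.speed_um_per_h
    codes = env.substrate_codes[agent.species]

    target = (
        env.packages.nearest(agent.position, spec.search_radius_um, codes)
        if codes
        else None
    )
    if target is None:
        try_move(agent, spec, env.grid, rng, dt, speed, cfg.boundary, cfg.max_retries)
        agent.hunger_clock_min += dt
    else:
        directed_move(
            agent, spec, env.grid, env.packages.positions[target], dt, speed, cfg.boundary
        )
        env.sync_agent(agent)  # neighbours see the post-move position
        eaten = env.packages.in_radius(agent.position, spec.eat_radius_um, codes)
        found: dict[str, np.ndarray] = {}
        for met in env.substrates_of[agent.species]:
            code = env.packages.met_code[met]
            ids = eaten[env.packages.met[eaten] == code]
            if len(ids) and env.packages.n[ids].sum() > 0:
                found[met] = ids
        if not found:
            agent.hunger_clock_min += dt
        else:
            ev.ate = True
            agent.hunger_clock_min = 0.0
            _metabolize(agent, spec, env, rng, found, dt_h, ev)

    daughter = check_division(agent, spec, env, rng)
    ev.divided = daughter is not None
    if check_death(agent, spec):
        env.kill(agent)
        ev.died = True
    agent.ate_last_step = ev.ate
    agent.mu_last = ev.mu if ev.ate else float("nan")
    return ev


def _metabolize(agent, spec, env, rng, found, dt_h, ev) -> None:
    """Uptake bounding, growth LP, pool updates for one fed agent."""
    masses = env.agent_masses_within(agent.position, spec.eat_radius_um)
    x_local = local_biomass_concentration(masses, spec.eat_radius_um)
    bounds: dict[str, float] = {}
    for met, ids in found.items():
        n_found = float(env.packages.n[ids].sum())
        d_c = delta_concentration(n_found, spec.eat_radius_um)
        exchange = env.config.metabolite(met).exchange_for(agent.species)
        bound = uptake_bound_from_intake(d_c, x_local, dt_h, spec.panel_max(exchange))
        if spec.uptake_mode == "kinetic":
            bound = min(bound, michaelis_menten_bound(d_c, spec.vmax, spec.km_mol_per_l))
        bounds[met] = bound

    sol = solve_growth(env.handles[agent.species], bounds)
    if not sol.feasible:
        return
    ev.mu = sol.mu
    m_g = agent.biomass_pg * PG_TO_G  # colony mass at the start of the step
    for met, ids in found.items():
        want = sol.v_s.get(met, 0.0) * 1e-3 * m_g * dt_h * AVOGADRO
        if want > 0:
            taken = env.packages.debit(ids, want)
            env.record_consumed(met, taken)
    for met, v_p in sol.v_p.items():
        if v_p <= 0:
            continue
        molecules = v_p * 1e-3 * m_g * dt_h * AVOGADRO
        env.record_produced(met, molecules)
        acc = agent.accumulators.get(met, 0.0) + molecules
        k = int(acc // env.config.package_size)
        if k > 0:
            pos = positions_in_sphere(rng, k, agent.position, spec.search_radius_um)
            from .spatial import apply_boundary

            pos = apply_boundary(pos, env.grid.dims_um, env.config.boundary)
            env.packages.add_many(met, pos, env.config.package_size)
            acc -= k * env.config.package_size
        agent.accumulators[met] = acc
    agent.biomass_pg = update_biomass(agent.biomass_pg, sol.mu, dt_h)
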