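"""Self-contained toy inputs: stoichiometric models and reference configs.

Everything here is synthetic and desk-scale. The toy networks are built so
that the FBA optimum has a closed form (µ = biomass yield × glucose uptake
bound), which makes simulated trajectories checkable analytically, and the
reference configurations encode the scenario geometry used throughout the
test suite: a 1 × 0.4 × 0.4 mm stirred micro-volume, Δt = 1 min, movement
speed 8000 µm/h.

Per-species physical values (cell dry mass 0.28 pg, radius 0.5 µm) are
E. coli-like defaults; colony aggregation factors and package sizes are
chosen per scenario as an accuracy/speed trade-off and are documented in
the methods note.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from cobra import Metabolite, Model, Reaction

from .core_types import CellSpec, FeedEvent, MetaboliteSpec, SimulationConfig
from .metabolism import MetabolicModelHandle

MW_GLUCOSE = 180.16
MW_ACETATE = 60.05
MW_BUTYRATE = 88.11

#: E. coli-like single-cell defaults (dry mass in pg, radius in µm)
CELL_MASS_PG = 0.28
CELL_RADIUS_UM = 0.5


def _rxn(model: Model, rid: str, mets: dict, lb: float = 0.0, ub: float = 1000.0,
         gpr: str = "") -> Reaction:
    r = Reaction(rid)
    r.lower_bound = lb
    r.upper_bound = ub
    model.add_reactions([r])
    r.add_metabolites(mets)
    if gpr:
        r.gene_reaction_rule = gpr
    return r


def toy_model(
    yield_biomass_g_per_mmol: float = 0.1,
    yield_acetate_mmol_per_mmol: float = 0.5,
) -> MetabolicModelHandle:
    """Three-reaction glucose → biomass + acetate network.

    FBA optimum: µ = yield_biomass × glucose uptake bound, acetate secretion
    = yield_acetate × glucose uptake bound (no internal caps).
    """
    if yield_biomass_g_per_mmol <= 0 or yield_acetate_mmol_per_mmol <= 0:
        raise ValueError("yields must be positive")
    m = Model("toy")
    glc = Metabolite("glc_e", name="glucose", compartment="e")
    ac = Metabolite("ac_e", name="acetate", compartment="e")
    x = Metabolite("biomass_c", name="biomass", compartment="c")
    _rxn(m, "EX_glc", {glc: -1.0})
    _rxn(m, "R_growth", {glc: -1.0, x: yield_biomass_g_per_mmol,
                         ac: yield_acetate_mmol_per_mmol})
    _rxn(m, "EX_ac", {ac: -1.0})
    _rxn(m, "EX_biomass", {x: -1.0})
    m.objective = "EX_biomass"
    return MetabolicModelHandle(
        model=m,
        biomass_reaction_id="EX_biomass",
        exchange_map={"glc": "EX_glc", "ac": "EX_ac"},
    )


def toy_model_with_genes(
    yield_biomass_g_per_mmol: float = 0.1,
    yield_acetate_mmol_per_mmol: float = 0.5,
) -> MetabolicModelHandle:
    """Toy network with a gene-associated transport/growth/export chain.

    Genes: gT (glucose transport), gG1+gG2 (growth), gA (acetate export);
    expression-derived caps on T_glc limit achievable µ.
    """
    m = Model("toy_genes")
    glc_e = Metabolite("glc_e", compartment="e")
    glc_c = Metabolite("glc_c", compartment="c")
    ac_c = Metabolite("ac_c", compartment="c")
    ac_e = Metabolite("ac_e", compartment="e")
    x = Metabolite("biomass_c", compartment="c")
    _rxn(m, "EX_glc", {glc_e: -1.0})
    _rxn(m, "T_glc", {glc_e: -1.0, glc_c: 1.0}, gpr="gT")
    _rxn(m, "R_growth", {glc_c: -1.0, x: yield_biomass_g_per_mmol,
                         ac_c: yield_acetate_mmol_per_mmol}, gpr="gG1 and gG2")
    _rxn(m, "T_ac", {ac_c: -1.0, ac_e: 1.0}, gpr="gA")
    _rxn(m, "EX_ac", {ac_e: -1.0})
    _rxn(m, "EX_biomass", {x: -1.0})
    m.objective = "EX_biomass"
    return MetabolicModelHandle(
        model=m,
        biomass_reaction_id="EX_biomass",
        exchange_map={"glc": "EX_glc", "ac": "EX_ac"},
    )


def cross_feeding_pair() -> tuple[MetabolicModelHandle, MetabolicModelHandle]:
    """Producer/consumer pair for emergent cross-feeding.

    Species A converts glucose to biomass with obligate acetate secretion
    (coupled stoichiometry). Species B grows on glucose with a small
    butyrate yield and on acetate with a large one, so butyrate output in
    co-culture with A exceeds its glucose-only monoculture output.
    """
    a = Model("species_A")
    glc = Metabolite("glc_e", compartment="e")
    ac = Metabolite("ac_e", compartment="e")
    xa = Metabolite("biomass_c", compartment="c")
    _rxn(a, "EX_glc", {glc: -1.0})
    _rxn(a, "R_growth", {glc: -1.0, xa: 0.1, ac: 0.5})
    _rxn(a, "EX_ac", {ac: -1.0})
    _rxn(a, "EX_biomass", {xa: -1.0})
    a.objective = "EX_biomass"
    handle_a = MetabolicModelHandle(
        model=a, biomass_reaction_id="EX_biomass",
        exchange_map={"glc": "EX_glc", "ac": "EX_ac"},
    )

    b = Model("species_B")
    glc_b = Metabolite("glc_e", compartment="e")
    ac_b = Metabolite("ac_e", compartment="e")
    but = Metabolite("but_e", compartment="e")
    xb = Metabolite("biomass_c", compartment="c")
    _rxn(b, "EX_glc", {glc_b: -1.0})
    _rxn(b, "EX_ac", {ac_b: -1.0})
    _rxn(b, "R_glc", {glc_b: -1.0, xb: 0.05, but: 0.1})
    _rxn(b, "R_ac", {ac_b: -1.0, xb: 0.08, but: 0.6})
    _rxn(b, "EX_but", {but: -1.0})
    _rxn(b, "EX_biomass", {xb: -1.0})
    b.objective = "EX_biomass"
    handle_b = MetabolicModelHandle(
        model=b, biomass_reaction_id="EX_biomass",
        exchange_map={"glc": "EX_glc", "ac": "EX_ac", "but": "EX_but"},
    )
    return handle_a, handle_b


def synthetic_expression(
    handle: MetabolicModelHandle,
    profile: Optional[dict[str, str]] = None,
    high: float = 100.0,
    low: float = 0.05,
) -> dict[str, float]:
    """Expression table covering every model gene (default all high)."""
    profile = profile or {}
    table: dict[str, float] = {}
    for g in handle.genes():
        level = profile.get(g, "high")
        if isinstance(level, str):
            table[g] = {"high": high, "low": low}[level]
        else:
            table[g] = float(level)
    return table


# ---------------------------------------------------------------------------
# Reference configurations
# ---------------------------------------------------------------------------

def _species(name: str, *, colony_size: int, env_volume_l: float, n_agents: int,
             **kwargs) -> CellSpec:
    unit_g = colony_size * CELL_MASS_PG * 1e-12
    defaults = dict(
        name=name,
        radius_um=CELL_RADIUS_UM,
        mass_pg=CELL_MASS_PG,
        initial_biomass_g_per_l=n_agents * unit_g / env_volume_l,
    )
    defaults.update(kwargs)
    return CellSpec(**defaults)


def exponential_growth_config(
    seed: int = 0,
    n_agents: int = 20,
    glucose_panel_max: float = 10.0,
    t_end_min: float = 100.0,
) -> tuple[SimulationConfig, dict[str, MetabolicModelHandle]]:
    """Non-limiting batch: every agent eats every step at the panel bound.

    Glucose packages (10 g/l at 1e12 molecules each, ≈5350 packages) are
    dense enough that a search radius of 50 µm practically guarantees a
    find, and each package holds orders of magnitude more substrate than
    one colony can consume, so total biomass should track x₀·e^{µt} with
    µ = 0.1 × panel bound exactly, up to the (astronomically rare) missed
    find.
    """
    dims = (1000.0, 400.0, 400.0)
    vol_l = dims[0] * dims[1] * dims[2] * 1e-15
    colony = 10
    spec = _species(
        "bacteria",
        colony_size=colony,
        env_volume_l=vol_l,
        n_agents=n_agents,
        search_radius_um=50.0,
        eat_radius_um=10.0,
        survive_time_min=30.0,
        substrates=("glc",),
        max_uptake={"EX_glc": glucose_panel_max},
    )
    cfg = SimulationConfig(
        env_dims_um=dims,
        dt_min=1.0,
        t_end_min=t_end_min,
        species=[spec],
        metabolites=[
            MetaboliteSpec("glc", "EX_glc", MW_GLUCOSE, 10.0, is_substrate=True),
            MetaboliteSpec("ac", "EX_ac", MW_ACETATE, 0.0, is_substrate=False),
        ],
        package_size=1e12,
        colony_size=colony,
        seed=seed,
    )
    return cfg, {"bacteria": toy_model()}


def batch_config(seed: int = 0, t_end_min: float = 200.0) -> tuple[
    SimulationConfig, dict[str, MetabolicModelHandle]
]:
    """Depleting batch that traverses all five growth phases.

    Packages (2e12 molecules) are sized so one colony (1e5 cells, 2.8e-8 g)
    consumes about one package per step; glucose runs out near 110 min,
    after which the population sits starved (stationary) until the
    20-minute survive time fells it (death phase).
    """
    dims = (1000.0, 400.0, 400.0)
    vol_l = dims[0] * dims[1] * dims[2] * 1e-15
    colony = 100_000
    spec = _species(
        "bacteria",
        colony_size=colony,
        env_volume_l=vol_l,
        n_agents=12,
        search_radius_um=50.0,
        eat_radius_um=10.0,
        survive_time_min=20.0,
        substrates=("glc",),
        max_uptake={"EX_glc": 10.0},
    )
    cfg = SimulationConfig(
        env_dims_um=dims,
        dt_min=1.0,
        t_end_min=t_end_min,
        species=[spec],
        metabolites=[
            MetaboliteSpec("glc", "EX_glc", MW_GLUCOSE, 10.0, is_substrate=True),
            MetaboliteSpec("ac", "EX_ac", MW_ACETATE, 0.0, is_substrate=False),
        ],
        package_size=2e12,
        colony_size=colony,
        seed=seed,
    )
    return cfg, {"bacteria": toy_model()}


def monod_config(
    seed: int = 0,
    km_mol_per_l: float = 2.72e-6,
    vmax: float = 10.0,
    t_end_min: float = 100.0,
) -> tuple[SimulationConfig, dict[str, MetabolicModelHandle]]:
    """Kinetic-uptake batch for recovering the imposed Km from µ vs C.

    Single-cell agents in a 150 µm cube with the 5e5-molecule package
    default; at C = Km an eating volume holds ≈110 packages, so the locally
    sensed concentration tracks the bulk within a few percent and the
    population-mean µ(C) follows vmax·yield·C/(Km + C). Periodic boundaries
    emulate a bulk sample of a larger stirred volume: with reflective walls
    the eating spheres of near-wall agents would be truncated and the
    sensed concentration systematically biased low.
    """
    dims = (150.0, 150.0, 150.0)
    vol_l = dims[0] ** 3 * 1e-15
    c0_mol = 2e-5  # ≈7.4 Km, decelerating phase traverses the Km range
    spec = _species(
        "bacteria",
        colony_size=1,
        env_volume_l=vol_l,
        n_agents=20,
        search_radius_um=30.0,
        eat_radius_um=20.0,
        survive_time_min=30.0,
        substrates=("glc",),
        uptake_mode="kinetic",
        vmax=vmax,
        km_mol_per_l=km_mol_per_l,
    )
    cfg = SimulationConfig(
        env_dims_um=dims,
        dt_min=1.0,
        t_end_min=t_end_min,
        species=[spec],
        metabolites=[
            MetaboliteSpec("glc", "EX_glc", MW_GLUCOSE, c0_mol * MW_GLUCOSE,
                           is_substrate=True),
            MetaboliteSpec("ac", "EX_ac", MW_ACETATE, 0.0, is_substrate=False),
        ],
        package_size=5e5,
        colony_size=1,
        seed=seed,
        boundary="periodic",
    )
    return cfg, {"bacteria": toy_model()}


def cross_feeding_config(
    co_culture: bool = True, seed: int = 0, t_end_min: float = 90.0
) -> tuple[SimulationConfig, dict[str, MetabolicModelHandle]]:
    """Producer/consumer co-culture (or consumer monoculture) on glucose."""
    dims = (400.0, 200.0, 200.0)
    vol_l = dims[0] * dims[1] * dims[2] * 1e-15
    colony = 1000
    handle_a, handle_b = cross_feeding_pair()
    common = dict(
        colony_size=colony,
        env_volume_l=vol_l,
        n_agents=29,
        search_radius_um=40.0,
        eat_radius_um=20.0,
        survive_time_min=30.0,
    )
    species = []
    models = {}
    if co_culture:
        species.append(
            _species("producer", substrates=("glc",),
                     max_uptake={"EX_glc": 10.0}, **common)
        )
        models["producer"] = handle_a
    species.append(
        _species("consumer", substrates=("glc", "ac"),
                 max_uptake={"EX_glc": 10.0, "EX_ac": 10.0}, **common)
    )
    models["consumer"] = handle_b
    cfg = SimulationConfig(
        env_dims_um=dims,
        dt_min=1.0,
        t_end_min=t_end_min,
        species=species,
        metabolites=[
            MetaboliteSpec("glc", "EX_glc", MW_GLUCOSE, 5.0, is_substrate=True),
            MetaboliteSpec("ac", "EX_ac", MW_ACETATE, 0.0, is_substrate=True),
            MetaboliteSpec("but", "EX_but", MW_BUTYRATE, 0.0, is_substrate=False),
        ],
        package_size=2e11,
        colony_size=colony,
        seed=seed,
    )
    return cfg, models


def starvation_config(
    mode: str = "point",
    seed: int = 0,
    t_end_min: float = 12.0,
    speed_um_per_h: float = 8000.0,
    env_dims_um: tuple[float, float, float] = (1000.0, 400.0, 400.0),
) -> tuple[SimulationConfig, dict[str, MetabolicModelHandle]]:
    """High-density microbioreactor with a 10 g/l glucose injection at t=0.

    60 g/l of colony-aggregated biomass (20,000 cells per agent → 1714
    agents in the 0.16 µl cube); glucose arrives as a feed event, either
    homogeneously or at the point (500, 0, 0). Starvation depends only on
    substrate finding, so the toy metabolism suffices.
    """
    vol_l = float(np.prod(env_dims_um)) * 1e-15
    colony = 20_000
    unit_g = colony * CELL_MASS_PG * 1e-12
    n_agents = int(round(60.0 * vol_l / unit_g))
    spec = _species(
        "ecoli",
        colony_size=colony,
        env_volume_l=vol_l,
        n_agents=n_agents,
        search_radius_um=20.0,
        eat_radius_um=5.0,
        survive_time_min=30.0,
        substrates=("glc",),
        max_uptake={"EX_glc": 1000.0},
    )
    feed = FeedEvent(
        time_min=0.0,
        metabolite="glc",
        amount_g_per_l=10.0,
        mode=mode,
        point_um=(env_dims_um[0] / 2.0, 0.0, 0.0) if mode == "point" else None,
    )
    cfg = SimulationConfig(
        env_dims_um=env_dims_um,
        dt_min=1.0,
        t_end_min=t_end_min,
        species=[spec],
        metabolites=[
            MetaboliteSpec("glc", "EX_glc", MW_GLUCOSE, 0.0, is_substrate=True),
            MetaboliteSpec("ac", "EX_ac", MW_ACETATE, 0.0, is_substrate=False),
        ],
        feeding=[feed],
        speed_um_per_h=speed_um_per_h,
        package_size=1e11,
        colony_size=colony,
        seed=seed,
    )
    return cfg, {"ecoli": toy_model()}
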