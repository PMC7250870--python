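"""Shared domain types, unit conventions, and the simulation configuration.

Units are fixed package-wide:

* lengths in µm, volumes in µm³ (1 µm³ = 1e-15 l),
* time in minutes internally; fluxes in mmol/gDW/h (converted via ``dt/60``),
* masses in pg for single agents, gDW for flux normalisation,
* extracellular concentrations reported in g/l; intracellular bookkeeping
  (uptake-bound arithmetic) in mol/l,
* metabolite amounts as molecule counts (float64).

The configuration below replaces the original tool's GUI panel: every panel
field is an explicit, documented attribute with the published defaults
(Δt = 1 min, movement speed 8000 µm/h, 5×10⁵ molecules per metabolite
package, glucose panel maximum 1000 mmol/gDW/h).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Avogadro constant, 1/mol.
AVOGADRO = 6.022e23
#: 1 µm³ in litres.
UM3_TO_L = 1e-15
#: 1 pg in grams.
PG_TO_G = 1e-12

UPTAKE_MODES = ("fixed_bound", "kinetic", "expression")
CELL_SHAPES = ("cocci", "bacilli")
FEED_MODES = ("homogeneous", "point")
BOUNDARIES = ("reflective", "periodic")


def sphere_volume_um3(radius_um: float) -> float:
    return 4.0 / 3.0 * math.pi * radius_um**3


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass
class CellSpec:
    """Per-species physical and behavioural parameters.

    ``mass_pg`` is the average dry mass of one real cell; one simulated agent
    aggregates ``colony_size`` (a :class:`SimulationConfig` field) such cells.
    ``max_uptake`` maps exchange-reaction ids to the panel upper bound in
    mmol/gDW/h (default 1000, the published glucose panel value).
    """

    name: str
    radius_um: float
    mass_pg: float
    search_radius_um: float
    eat_radius_um: float
    survive_time_min: float
    shape: str = "cocci"
    length_um: Optional[float] = None  # bacilli only, total capsule length
    volume_um3: Optional[float] = None
    speed_um_per_h: Optional[float] = None  # falls back to the global speed
    model_path: Optional[str] = None
    initial_biomass_g_per_l: float = 0.0
    substrates: tuple[str, ...] = ()
    max_uptake: dict[str, float] = field(default_factory=dict)
    default_max_uptake: float = 1000.0
    uptake_mode: str = "fixed_bound"
    vmax: Optional[float] = None  # mmol/gDW/h, kinetic mode
    km_mol_per_l: Optional[float] = None  # kinetic mode
    expression_path: Optional[str] = None  # expression mode
    expression_scale: float = 1.0

    def __post_init__(self) -> None:
        self.substrates = tuple(self.substrates)
        if self.volume_um3 is None:
            self.volume_um3 = sphere_volume_um3(self.radius_um)

    def panel_max(self, exchange_id: str) -> float:
        return self.max_uptake.get(exchange_id, self.default_max_uptake)


@dataclass
class MetaboliteSpec:
    """One extracellular metabolite and its unit bridge (counts ↔ g/l)."""

    id: str
    exchange_id: str
    mw_g_per_mol: float
    initial_concentration_g_per_l: float = 0.0
    is_substrate: bool = False
    #: optional per-species exchange-reaction overrides
    exchange_overrides: dict[str, str] = field(default_factory=dict)

    def exchange_for(self, species: str) -> str:
        return self.exchange_overrides.get(species, self.exchange_id)


@dataclass
class FeedEvent:
    """A substrate addition: homogeneous over the cube or at a single point."""

    time_min: float
    metabolite: str
    amount_g_per_l: float
    mode: str = "homogeneous"
    point_um: Optional[tuple[float, float, float]] = None


@dataclass
class SimulationConfig:
    env_dims_um: tuple[float, float, float]
    dt_min: float
    t_end_min: float
    species: list[CellSpec]
    metabolites: list[MetaboliteSpec]
    feeding: list[FeedEvent] = field(default_factory=list)
    speed_um_per_h: float = 8000.0
    package_size: float = 5e5
    colony_size: int = 1000
    seed: int = 0
    boundary: str = "reflective"
    max_retries: int = 10
    record_every: int = 1

    def __post_init__(self) -> None:
        self.env_dims_um = tuple(float(d) for d in self.env_dims_um)

    @property
    def volume_l(self) -> float:
        return float(np.prod(self.env_dims_um)) * UM3_TO_L

    def metabolite(self, met_id: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)


@dataclass
class CellAgent:
    """One colony-aggregated individual.

    ``biomass_pg`` is the total dry mass of the colony; ``hunger_clock_min``
    counts time since the agent last ate, and drives starvation death.
    ``accumulators`` carries secreted molecules that have not yet filled a
    whole metabolite package.
    """

    id: int
    species: str
    position: np.ndarray
    biomass_pg: float
    direction: np.ndarray
    hunger_clock_min: float = 0.0
    alive: bool = True
    occupied: frozenset = frozenset()
    accumulators: dict[str, float] = field(default_factory=dict)
    ate_last_step: bool = False
    mu_last: float = float("nan")


@dataclass
class MetabolitePackage:
    """A mobile parcel of ``n`` molecules of one metabolite (point object)."""

    id: int
    metabolite: str
    position: np.ndarray
    n: float


# ---------------------------------------------------------------------------
# Validation and initial counts
# ---------------------------------------------------------------------------

def _point_inside(point: Sequence[float], dims: Sequence[float]) -> bool:
    return all(0.0 <= p <= d for p, d in zip(point, dims))


def validate_config(config: SimulationConfig) -> list[str]:
    """Check every configuration invariant; return one message per violation.

    Pure: does not mutate the config. An empty list means the configuration
    is ready to run.
    """
    v: list[str] = []
    if len(config.env_dims_um) != 3 or any(d <= 0 for d in config.env_dims_um):
        v.append("env_dims_um: all three edge lengths must be > 0")
    if config.dt_min <= 0:
        v.append("dt_min: time step must be > 0")
    if config.t_end_min <= 0:
        v.append("t_end_min: horizon must be > 0")
    if config.package_size < 1:
        v.append("package_size: must be >= 1 molecule")
    if config.colony_size < 1:
        v.append("colony_size: must be >= 1 cell per agent")
    if config.speed_um_per_h < 0:
        v.append("speed_um_per_h: must be >= 0")
    if config.boundary not in BOUNDARIES:
        v.append(f"boundary: must be one of {BOUNDARIES}")
    if config.record_every < 1:
        v.append("record_every: must be >= 1")
    if config.max_retries < 1:
        v.append("max_retries: must be >= 1")

    met_ids = {m.id for m in config.metabolites}
    for m in config.metabolites:
        if m.mw_g_per_mol <= 0:
            v.append(f"metabolites[{m.id}].mw_g_per_mol: must be > 0")
        if m.initial_concentration_g_per_l < 0:
            v.append(f"metabolites[{m.id}].initial_concentration_g_per_l: must be >= 0")

    names = set()
    for s in config.species:
        if s.name in names:
            v.append(f"species[{s.name}].name: duplicate species name")
        names.add(s.name)
        if s.shape not in CELL_SHAPES:
            v.append(f"species[{s.name}].shape: must be one of {CELL_SHAPES}")
        for fld in ("radius_um", "mass_pg", "volume_um3"):
            val = getattr(s, fld)
            if val is None or val <= 0:
                v.append(f"species[{s.name}].{fld}: must be > 0")
        if s.shape == "bacilli" and (s.length_um is None or s.length_um <= 0):
            v.append(f"species[{s.name}].length_um: bacilli need a length > 0")
        if s.search_radius_um <= 0:
            v.append(f"species[{s.name}].search_radius_um: must be > 0")
        if s.eat_radius_um <= 0:
            v.append(f"species[{s.name}].eat_radius_um: must be > 0")
        if s.eat_radius_um > s.search_radius_um:
            v.append(
                f"species[{s.name}].eat_radius_um: must be <= search_radius_um"
            )
        if s.survive_time_min <= 0:
            v.append(f"species[{s.name}].survive_time_min: must be > 0")
        if s.speed_um_per_h is not None and s.speed_um_per_h < 0:
            v.append(f"species[{s.name}].speed_um_per_h: must be >= 0")
        if s.initial_biomass_g_per_l < 0:
            v.append(f"species[{s.name}].initial_biomass_g_per_l: must be >= 0")
        if s.uptake_mode not in UPTAKE_MODES:
            v.append(f"species[{s.name}].uptake_mode: must be one of {UPTAKE_MODES}")
        if s.uptake_mode == "kinetic":
            if s.vmax is None or s.vmax <= 0:
                v.append(f"species[{s.name}].vmax: kinetic mode needs vmax > 0")
            if s.km_mol_per_l is None or s.km_mol_per_l <= 0:
                v.append(f"species[{s.name}].km_mol_per_l: kinetic mode needs Km > 0")
        if s.uptake_mode == "expression" and not s.expression_path:
            v.append(
                f"species[{s.name}].expression_path: expression mode needs a table path"
            )
        for sub in s.substrates:
            if sub not in met_ids:
                v.append(f"species[{s.name}].substrates: unknown metabolite '{sub}'")

    for i, f in enumerate(config.feeding):
        if f.time_min < 0:
            v.append(f"feeding[{i}].time_min: must be >= 0")
        if f.amount_g_per_l <= 0:
            v.append(f"feeding[{i}].amount_g_per_l: must be > 0")
        if f.metabolite not in met_ids:
            v.append(f"feeding[{i}].metabolite: unknown metabolite '{f.metabolite}'")
        if f.mode not in FEED_MODES:
            v.append(f"feeding[{i}].mode: must be one of {FEED_MODES}")
        if f.mode == "point":
            if f.point_um is None:
                v.append(f"feeding[{i}].point_um: point mode needs coordinates")
            elif not _point_inside(f.point_um, config.env_dims_um):
                v.append(f"feeding[{i}].point_um: point outside environment")
    return v


def molecules_from_concentration(
    conc_g_per_l: float, mw_g_per_mol: float, volume_l: float
) -> float:
    """Molecule count equivalent to a bulk concentration over a volume."""
    return conc_g_per_l / mw_g_per_mol * AVOGADRO * volume_l


def concentration_from_molecules(
    n: float, mw_g_per_mol: float, volume_l: float
) -> float:
    return n * mw_g_per_mol / (AVOGADRO * volume_l)


def initial_counts(
    config: SimulationConfig,
) -> tuple[dict[str, int], dict[str, int]]:
    """Initial object counts from the configured bulk concentrations.

    packages = round(C0/MW · N_A · V / package_size),
    agents   = round(X0 · V / (mass · colony_size)),
    rounding half-up, so realised totals differ from nominal concentrations
    by less than one package/agent quantum.
    """
    vol = config.volume_l
    if vol <= 0:
        raise ValueError("environment volume must be positive")
    agents = {
        s.name: round_half_up(
            s.initial_biomass_g_per_l
            * vol
            / (s.mass_pg * PG_TO_G * config.colony_size)
        )
        for s in config.species
    }
    packages = {
        m.id: round_half_up(
            molecules_from_concentration(
                m.initial_concentration_g_per_l, m.mw_g_per_mol, vol
            )
            / config.package_size
        )
        for m in config.metabolites
    }
    return agents, packages
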