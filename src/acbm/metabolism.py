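"""Uptake bounding, the growth LP, and biomass/metabolite pool updates.

The coupling between the spatial layer and the stoichiometric model runs:

1. molecules found in the eating volume → a local concentration change
   ΔC = n / (N_A·V), with V the eating sphere;
2. ΔC → an uptake-rate upper bound v = ΔC / (x·Δt), capped by the panel
   maximum (and, in kinetic mode, by the Michaelis–Menten rate at ΔC);
3. FBA maximising biomass under those bounds → µ, uptake and secretion
   rates;
4. pool updates: x_{i+1} = x_i·e^{µΔt}, C_{i+1} = C_i ± v·x_i·Δt.

Fluxes are mmol/gDW/h throughout (hence the ×1000 mol→mmol factor in the
intake bound); uptake and secretion rates are reported positive.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core_types import AVOGADRO, UM3_TO_L, PG_TO_G, sphere_volume_um3

#: growth rates below this are treated as "no growth" (LP noise floor)
MU_TOLERANCE = 1e-9


@dataclass
class MetabolicModelHandle:
    """A stoichiometric model plus the plumbing the simulator needs.

    ``exchange_map`` maps metabolite ids (the simulator's names) to exchange
    reaction ids in this model. Only mapped exchanges are driven by the
    environment; their uptake (negative-flux) direction is closed between
    solves so a cell can only import what it has eaten.
    """

    model: "cobra.Model"  # noqa: F821
    biomass_reaction_id: str
    exchange_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biomass_reaction_id not in [r.id for r in self.model.reactions]:
            raise ValueError(
                f"biomass reaction '{self.biomass_reaction_id}' not in model"
            )
        rxn_ids = {r.id for r in self.model.reactions}
        for met, ex in self.exchange_map.items():
            if ex not in rxn_ids:
                raise ValueError(f"exchange '{ex}' for metabolite '{met}' not in model")
        self.model.objective = self.biomass_reaction_id
        for ex in self.exchange_map.values():
            rxn = self.model.reactions.get_by_id(ex)
            rxn.lower_bound = max(rxn.lower_bound, 0.0)

    def genes(self) -> list[str]:
        return [g.id for g in self.model.genes]

    def set_exchange_map(self, exchange_map: Mapping[str, str]) -> None:
        """Rebind the metabolite → exchange-reaction map (validated).

        Uptake directions of newly mapped exchanges are closed so the
        environment stays the only source of importable substrate.
        """
        rxn_ids = {r.id for r in self.model.reactions}
        for met, ex in exchange_map.items():
            if ex not in rxn_ids:
                raise ValueError(f"exchange '{ex}' for metabolite '{met}' not in model")
        self.exchange_map = dict(exchange_map)
        for ex in self.exchange_map.values():
            rxn = self.model.reactions.get_by_id(ex)
            rxn.lower_bound = max(rxn.lower_bound, 0.0)


@dataclass
class FluxSolution:
    """FBA result: specific growth rate plus mapped exchange rates.

    ``v_s`` holds substrate uptake rates and ``v_p`` product secretion rates,
    both positive, in mmol/gDW/h, keyed by metabolite id.
    """

    mu: float
    v_s: dict[str, float]
    v_p: dict[str, float]
    feasible: bool


# ---------------------------------------------------------------------------
# Uptake bounds
# ---------------------------------------------------------------------------

def delta_concentration(n: float, eat_radius_um: float) -> float:
    """Concentration change (mol/l) of n molecules over the eating sphere."""
    if eat_radius_um <= 0:
        raise ValueError("eat radius must be positive")
    if n < 0:
        raise ValueError("molecule count must be non-negative")
    v_l = sphere_volume_um3(eat_radius_um) * UM3_TO_L
    return n / (AVOGADRO * v_l)


def local_biomass_concentration(
    masses_pg: "list[float] | np.ndarray", eat_radius_um: float
) -> float:
    """Biomass concentration (gDW/l) of the agents in an eating volume."""
    v_l = sphere_volume_um3(eat_radius_um) * UM3_TO_L
    return float(np.sum(masses_pg)) * PG_TO_G / v_l


def uptake_bound_from_intake(
    delta_c_mol_per_l: float, x_gdw_per_l: float, dt_h: float, panel_max: float
) -> float:
    """Uptake upper bound v = ΔC/(x·Δt) in mmol/gDW/h, capped at the panel value."""
    if x_gdw_per_l <= 0:
        raise ValueError("local biomass concentration must be positive")
    if dt_h <= 0:
        raise ValueError("time step must be positive")
    return min(1000.0 * delta_c_mol_per_l / (x_gdw_per_l * dt_h), panel_max)


def michaelis_menten_bound(c_mol_per_l: float, vmax: float, km_mol_per_l: float) -> float:
    """Michaelis–Menten uptake cap vmax·C/(Km + C), mmol/gDW/h."""
    if c_mol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    if vmax <= 0 or km_mol_per_l <= 0:
        raise ValueError("vmax and Km must be positive")
    return vmax * c_mol_per_l / (km_mol_per_l + c_mol_per_l)


# ---------------------------------------------------------------------------
# Expression-derived bounds (simplified transcriptional constraint)
# ---------------------------------------------------------------------------

def apply_expression_bounds(
    handle: MetabolicModelHandle,
    expression: Mapping[str, float],
    scale: float,
) -> MetabolicModelHandle:
    """Cap reaction rates in proportion to the expression of their genes.

    For every reaction with a gene association whose genes appear in the
    table, the upper bound becomes ``scale × Σ expression``; originally
    reversible reactions are bounded symmetrically. Reactions with no
    expressed-gene data keep their bounds. This is a deliberately simplified
    transcriptional constraint: it reproduces the expression-proportional
    rate caps of TRFBA-style methods without the full regulatory update
    loop. Returns a new handle on a copy of the model.
    """
    if not expression:
        raise ValueError("expression table is empty")
    model = handle.model.copy()
    for rxn in model.reactions:
        genes = [g.id for g in rxn.genes]
        levels = [expression[g] for g in genes if g in expression]
        if not levels:
            continue
        bound = scale * float(sum(levels))
        rxn.upper_bound = bound
        if rxn.lower_bound < 0:
            rxn.lower_bound = -bound
    return MetabolicModelHandle(
        model=model,
        biomass_reaction_id=handle.biomass_reaction_id,
        exchange_map=dict(handle.exchange_map),
    )


# ---------------------------------------------------------------------------
# Growth LP
# ---------------------------------------------------------------------------

def solve_growth(
    handle: MetabolicModelHandle, uptake_bounds: Mapping[str, float]
) -> FluxSolution:
    """Maximise biomass with the given per-metabolite uptake bounds.

    ``uptake_bounds`` maps metabolite ids to allowed uptake (≥ 0,
    mmol/gDW/h); mapped metabolites not listed get an uptake of zero.
    Infeasible problems and growth below tolerance come back as
    ``feasible=False`` with all rates zero; genuine solver failures raise.
    """
    model = handle.model
    for met, ex in handle.exchange_map.items():
        bound = float(uptake_bounds.get(met, 0.0))
        if bound < 0:
            raise ValueError(f"uptake bound for '{met}' must be >= 0")
        model.reactions.get_by_id(ex).lower_bound = -bound
    try:
        sol = model.optimize()
    except Exception as exc:  # pragma: no cover - solver-level failure
        raise RuntimeError(f"LP solver failure: {exc}") from exc
    zero = FluxSolution(0.0, {m: 0.0 for m in handle.exchange_map},
                        {m: 0.0 for m in handle.exchange_map}, False)
    if sol.status != "optimal":
        return zero
    mu = float(sol.objective_value)
    if mu < MU_TOLERANCE:
        return zero
    v_s, v_p = {}, {}
    for met, ex in handle.exchange_map.items():
        flux = float(sol.fluxes[ex])
        v_s[met] = max(-flux, 0.0)
        v_p[met] = max(flux, 0.0)
    return FluxSolution(mu, v_s, v_p, True)


# ---------------------------------------------------------------------------
# Pool updates
# ---------------------------------------------------------------------------

def update_biomass(x_i: float, mu: float, dt_h: float) -> float:
    """Exponential biomass update x_{i+1} = x_i·e^{µΔt}."""
    return x_i * math.exp(mu * dt_h)


def update_product(
    c_i_g_per_l: float, v_p: float, x_i_gdw_per_l: float, dt_h: float, mw_g_per_mol: float
) -> float:
    """Product pool update C_{i+1} = C_i + v_p·x_i·Δt, reported in g/l."""
    return c_i_g_per_l + v_p * x_i_gdw_per_l * dt_h * mw_g_per_mol / 1000.0


def update_substrate(
    c_i_g_per_l: float, v_s: float, x_i_gdw_per_l: float, dt_h: float, mw_g_per_mol: float
) -> float:
    """Substrate pool update C_{i+1} = C_i − v_s·x_i·Δt, clamped at zero.

    A negative result can only arise through rounding of the molecule
    bookkeeping; it is clamped with a warning.
    """
    c = c_i_g_per_l - v_s * x_i_gdw_per_l * dt_h * mw_g_per_mol / 1000.0
    if c < 0:
        import warnings

        warnings.warn("substrate update overshot zero; clamping", stacklevel=2)
        c = 0.0
    return c


def spawn_product_packages(
    mass_produced_g: float,
    mw_g_per_mol: float,
    package_size: float,
    position: np.ndarray,
    placement_radius_um: float,
    rng: np.random.Generator,
    carry_molecules: float = 0.0,
) -> tuple[list[tuple[np.ndarray, float]], float]:
    """Turn secreted mass into packages placed around the producing agent.

    Molecules accumulate on top of ``carry_molecules``; whole packages are
    emitted at uniform positions within ``placement_radius_um`` of the agent
    and the sub-package remainder is returned for the caller to carry.
    Emitted + remainder always equals input (conservation).
    """
    if mass_produced_g < 0:
        raise ValueError("produced mass must be non-negative")
    from .spatial import positions_in_sphere

    molecules = carry_molecules + mass_produced_g / mw_g_per_mol * AVOGADRO
    k = int(molecules // package_size)
    remainder = molecules - k * package_size
    if k == 0:
        return [], remainder
    pos = positions_in_sphere(rng, k, position, placement_radius_um)
    return [(pos[i], package_size) for i in range(k)], remainder
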