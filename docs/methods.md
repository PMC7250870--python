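# Methods

## Model overview and assumptions

`acbm` couples an agent-based spatial layer to constraint-based metabolism.
The assumptions, in order of importance:

* **Steady-state metabolism within a step.** Each fed agent's growth and
  exchange rates come from FBA (biomass maximisation) of its species'
  stoichiometric model, re-solved every time step under bounds derived
  from what the agent just found. One LP per fed agent per step; starved
  agents skip the LP entirely and only move.
* **Convection-dominated transport.** The volume models a well-stirred
  reactor sample: metabolite packages and cells travel ballistically at a
  fixed speed along random directions each step. There is no diffusion
  PDE, no chemotaxis, and no flow field; "stirring" is simply the package
  speed.
* **Colony aggregation.** One agent stands for `colony_size` real cells
  that eat, grow and divide together. This preserves population-level
  rates (bounds and consumption scale with colony biomass) at a fraction
  of the agent count, but collapses within-colony heterogeneity, and the
  aggregated colony still occupies only a single cell's mesh footprint —
  a deliberate physical inconsistency accepted for tractability.
* **Discrete extracellular quanta.** Metabolites exist as packages of
  `package_size` molecules. Locality of sensing (an agent "sees" only the
  molecules inside its eating sphere) is what differentiates individual
  agents; package size sets the granularity of that sensing.

## The per-step cell process

Death check (hunger ≥ survive time) → search (nearest consumable package
within the search radius, exact, ties to the lowest package id) → directed
move toward it at normal speed (capped at the target) or random move if
nothing was found → eat all substrate packages inside the eating radius →
uptake bounds → FBA → debit consumed molecules, emit products, exponential
biomass update → division check → death check. Agents are updated in an
order reshuffled every step with the run's generator, so no agent has a
systematic first claim on contested packages.

Decisions taken where the process was genuinely open:

* **Directed moves and collisions.** A blocked directed move backs off
  along its path in 1 µm decrements (up to 8), i.e. the cell stops just
  short of the blocker; a blocked random move redraws its direction up to
  `max_retries` (default 10) times and then stays put. A cell that finds a
  package beyond its eating radius but within its search radius may still
  eat in the same step if the move brings packages inside the eating
  radius.
* **Eat-then-return.** The uptake bound is computed from *all* molecules
  in the eating sphere, but only the molecules FBA actually uses are
  debited, nearest package first. This is equivalent to "eat everything,
  return the unused excess to where it came from" and conserves molecules
  exactly. Packages drained below one molecule are absorbed into the final
  debit — molecules are discrete, and without this cutoff near-empty
  packages would survive indefinitely as floating-point residue and keep
  resetting hunger clocks.
* **Which biomass enters the equations.** The uptake bound uses the local
  biomass concentration x (all agents inside the eating sphere — crowding
  shares the local substrate), while consumption and production use the
  eater's own colony biomass, aggregated globally for the reported g/l
  curves.
* **Division placement.** The daughter takes half the colony biomass and
  the nearest free element set, searching outward ring by ring (ties to
  the lowest flat element index) up to five cell diameters; failing that,
  division defers to the next step.
* **Secretion placement.** Whole packages are emitted uniformly within one
  search radius of the producer; sub-package remainders accrue in a
  per-agent accumulator (flushed at death so nothing is lost).
* **Random directions.** The two-angle construction
  d = (cos φ cos θ, cos φ sin θ, sin φ) with φ, θ ~ U[0, 2π) is kept
  literally even though it is *not* uniform on the sphere (|d_z| follows
  an arcsine law, so polar directions are over-represented). The motion
  model is defined by this construction; the bias is isotropic in the
  x–y plane and has zero mean, so displacement statistics (MSD ∝ t) are
  unaffected.
* **Boundaries.** Reflective walls by default (a closed vessel); periodic
  boundaries are a config option with minimum-image search throughout.

## Parameters that matter

| parameter | unit | default | rationale |
| --- | --- | --- | --- |
| Δt | min | 1 | short enough that x is ~constant within a step (the bound uses x_i) |
| speed | µm/h | 8000 | convective mixing scale; cells and packages share it |
| package_size | molecules | 5×10⁵ | sensing granularity vs object count trade-off; scenario configs scale it up so desk-scale runs stay at 10³–10⁵ packages |
| colony_size | cells/agent | 1000 | accuracy vs speed trade-off; scenario configs choose 1–2×10⁴ |
| search / eat radius | µm | per species | two independent fields (their relation is left to the user; eat ≤ search enforced) |
| survive time | min | per species | starvation-death horizon |
| panel max uptake | mmol/gDW/h | 1000 | effectively "no panel cap" unless set lower |
| µ tolerance | 1/h | 1e-9 | LP objective below this counts as no growth |

Per-species physical values (mass 0.28 pg, radius 0.5 µm in the fixtures)
are E. coli-like defaults; real studies should supply measured values.

## Unit bridges and numerical choices

Lengths µm, time minutes (hours inside flux arithmetic), fluxes mmol/gDW/h
(hence the ×1000 mol→mmol factor in the intake bound), concentrations
g/l via each metabolite's molecular weight, molecule counts as float64
(exact to well below one part in 10⁹ at the counts used). Initial counts
round half-up, so realised concentrations differ from nominal by less than
one package/agent quantum. N_A = 6.022×10²³/mol.

Two numerical caveats are inherent to the update scheme:

* **Exponential vs linear updates.** Biomass advances as x·e^{µΔt} while
  pools advance linearly (±v·x·Δt), so the stoichiometric budget closes
  only to O(µΔt/2) per step (≈0.4% at µ = 0.5/h, Δt = 1 min). The
  mass-balance test uses a low-rate run accordingly; at the published
  Δt = 1 min this stays below 1% for µ ≤ 1.2/h.
* **Wall truncation of the eating sphere.** Near a reflective wall part of
  the eating sphere lies outside the vessel, so the sensed concentration
  is biased low by up to ~r_eat/L. Irrelevant when r_eat ≪ L (the real
  bioreactor geometry), but material in a 150 µm test cube — the Monod
  scenario therefore uses periodic boundaries, which emulate a bulk
  sample of a larger stirred volume exactly.

Other choices: the spatial index is a per-step KD-tree with exact
post-filtering (equal to brute force by construction, ties to the lowest
id); Monod fits use nonlinear least squares initialised at
(max µ, median C) with 1e-10 parameter tolerance, all-equal rates reported
as a degenerate fit with K_s pinned below min(C)/100; the exponential-phase
window is the longest span whose local log-slopes stay within 10% of their
mean; Spearman p-values are exact (full permutation enumeration) for
n ≤ 10 and t-approximated above; the expression mode caps each
gene-associated reaction at scale × (summed expression of its genes),
reversible reactions symmetrically — a simplified transcriptional
constraint, not a full regulatory algorithm. A practical calibration for
the scale constant: choose it so the unconstrained-substrate µ matches an
observed exponential-phase µ.

## Batch-phase classification

Phases are read off the (lightly smoothed) biomass trajectory:
accelerating = growth under way before a constant log-slope is
established; log = the longest constant-log-slope window; decelerating =
sustained instantaneous rate below 0.9 of the log rate while biomass still
rises; stationary = |rate| below 0.1 of the log rate; death = sustained
decline off the peak. The simulated populations have no lag mechanism and
reach full rate within a step or two, so the accelerating span is brief by
construction: the first recorded interval, where a constant rate cannot
yet be established, is classified as accelerating.

## What the fixtures emulate — and what they do not

The toy networks (glucose → 0.1 biomass + 0.5 acetate per mmol, and a
producer/consumer pair where the consumer converts acetate to butyrate at
6× its glucose butyrate yield) have rational closed-form FBA optima, so
trajectories are checkable analytically. The scenario configs reproduce
the study geometries (0.16 µl cube, Δt = 1 min, 8000 µm/h, 10 g/l glucose,
60 g/l biomass for the starvation scenario at colony_size 2×10⁴ and
package_size 10¹¹) at desk scale: runs finish in seconds to a minute on
one CPU. Passing tests therefore demonstrate the *mechanics* — equation
fidelity, conservation, emergent starvation/cross-feeding patterns — not
genome-scale realism: toy models cannot show overflow metabolism, pathway
switching, or realistic by-product spectra, and scaled package sizes
coarsen spatial substrate gradients relative to the 5×10⁵-molecule
default. Genome-scale SBML models load through the same interface for
full-scale work.

## Known limitations

No diffusion (stirred systems only), no pH or organic-acid toxicity — in
long fermentations this inflates late growth; no lysis, sporulation or
signalling; the expression mode is static (one table per run); package
motion ignores excluded volume (packages are points); alternate FBA optima
are taken as the solver returns them (secretion splits among equivalent
pathways are solver-dependent in degenerate models, though not in the toy
fixtures); determinism is guaranteed per platform (same BLAS/solver
build), not across platforms.
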