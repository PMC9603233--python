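# Methods

## Scope and structure

`spraymix` models inhalation exposure from spraying a **binary**
(semi)-volatile liquid mixture in a well-mixed room, either released
freely ("room" mode) or directed at a wall ("wall" mode). Six building
blocks map onto the modules:

| module        | contents |
|---------------|----------|
| `physchem`    | components, saturation-pressure tables, activity models, mixture thermodynamics, transfer-coefficient helpers |
| `spray_source`| lognormal size classes, inhalable fraction, jet dynamics, impaction split |
| `aerosol`     | per-pulse rates: ventilation, Stokes settling, SRMM droplet evaporation |
| `surfaces`    | floor film and wall area elements with capped evaporation |
| `engine`      | scenario, pulse-superposition Euler scheme, TWA, mass audit |
| `stats`       | geometric bias, relative bias, Pearson/Spearman correlation |

plus `fixtures` (the packaged reference configurations) and a thin CLI.

## Model assumptions

* **Well-mixed room.** Released material disperses instantaneously and
  homogeneously; adequate for small/medium rooms, questionable for large
  or tall ones.
* **Pulse superposition.** Continuous spraying is approximated by pulses
  every `IM*dt` seconds carrying `rate*IM*dt` of liquid; the model is a
  sum of independent pulse states coupled only through the shared room
  vapour and films.
* **SRMM droplet evaporation.** No concentration gradient inside the
  droplet; per-component gas-side diffusion flux with Raoult's law,
  activity coefficients and finite far-field vapour (backpressure).
  Condensational growth is permitted when the room exceeds the surface
  equilibrium. All droplet-side properties are evaluated at the Hubbard
  reference temperature `T_r = T_dr + (T_room - T_dr)/3`; surface films
  use `T_room`. The droplet surface temperature `T_dr` is a user input.
* **Stokes settling** without slip or Reynolds corrections. Above ~50 µm
  the uncorrected law overestimates fall speeds; the package warns but
  applies it to all sizes (no published correction was adopted).
* **Impaction split.** A full-cone turbulent round jet with zero-slip
  entrainment gives the flow mean velocity at the wall; the impaction
  parameter `K` is a hard step: classes with `K >= 0.3` (evaluated at the
  class *median* diameter, constant during flight) deposit, others are
  overspray. The configured cone angle is the **full** opening angle; the
  jet equations use the half-angle, and the spray cross-section at the
  wall is the geometric cone `D(s) = D0 + 2 s tan(theta/2)`. Only this
  convention reproduces the ~202 µm critical diameter of the reference
  geometry from its printed inputs.
* **Films.** One pooled floor film (composition from the pooled masses);
  the sprayed wall is resolved into one area element per release pulse,
  filled left-to-right, each evaporating independently. Film evaporation
  demand is `area * beta_i * (C_eq,i - C_room,i)` clamped at zero — no
  condensation onto surfaces — and capped so a film empties exactly to
  zero: mass arriving on an exhausted film evaporates instantaneously.
  The demand is evaluated on the post-deposition pool `m + dt*inflow`, so
  that cap is meaningful on an empty film.
* **No** chemical reactions, droplet–droplet interaction, dermal
  exposure, multi-box rooms, or mixtures of more than two components.

## Key parameters

| parameter | units | default | meaning |
|-----------|-------|---------|---------|
| `dt`, `dt_post` | s | 0.2, 2.0 | Euler step during / after spraying |
| `IM`      | –     | 20      | pulse spacing in units of `dt` |
| `N_c`     | –     | 5       | droplet size classes (equal mass shares) |
| `K_crit`  | –     | 0.3     | impaction threshold |
| `beta_i`  | m/s   | per component | surface mass-transfer coefficient |
| `floor_evap_fraction` | – | 1.0 | floor area fraction active for evaporation |
| `d_min`, `mass_min` | m, kg | 0.5 µm, 1e-15 | pulse termination thresholds |

The published power-law correlation for `beta`
(`0.011 v^0.96 D^0.19 / (nu^0.14 X^0.04)`) is not dimensionally
consistent in SI units and cannot reproduce the reference values
(2.4e-3 / 2.2e-3 m/s for water / hydrogen peroxide); it is therefore
shipped only as a documented helper, and components carry `beta` as a
direct input.

Saturation pressures are supplied as per-component tables. Lookups
resolve to the nearest tabulated temperature within 5 K and fail loudly
beyond that, rather than extrapolating: the reference substance table
lists values at the room and droplet-surface temperatures only, and the
Hubbard reference temperature falls between them (the droplet-side entry
is the one used). A Magnus-type helper for water (0–40 °C) exists solely
to convert relative humidity to vapour concentrations when building
scenarios and never enters the core equations.

## Numerical scheme

Fully explicit Euler: every rate within a step reads the room vapour and
film state from the start of that step. After the last application
interval the step switches to `dt_post`, but reverts to `dt` while any
droplet pulse is alive, because droplet evaporation is stiff relative to
film evaporation.

Three guards keep the explicit scheme physical without altering the
model:

1. **Per-component budgets.** Ventilation + settling of a pulse is capped
   at the pulse mass; each component's evaporation is capped at that
   component's share of what remains. Without the per-component cap a
   droplet drying out within one step would "evaporate" part of its
   nonvolatile core into the vapour phase.
2. **Mass-based state update.** The per-pulse component masses are
   advanced directly, and diameter and composition are recomputed from
   the updated mole contents (ventilation/settling remove whole droplets,
   evaporation shrinks them). This reproduces the SRMM diameter and
   composition derivatives to first order in `dt` — the module-level
   derivative functions are verified against an independent mole-balance
   oracle in the tests — while keeping each component's balance exact
   under caps and clamps.
3. **Quasi-equilibrium residue closure.** A droplet with a nonvolatile
   core relaxes to its Raoult (hygroscopic) equilibrium at rate
   `k = 12 V̄ x_nv D_v p_v* γ_v / (d² R T_r)`, which exceeds `1/dt` once
   the particle is nearly dry; an explicit step is then unstable. For
   such pulses the composition is set directly to the equilibrium
   (solving `x γ(x) = C R T_r / (M p*)`), conserving the nonvolatile
   core exactly and exchanging the implied volatile mass with the room
   vapour, with a per-step absorption budget in supersaturated rooms.

A pulse terminates when its diameter falls below 0.5 µm (the SRMM is
singular at `d -> 0`) or its mass below 1e-15 kg; residual volatile mass
joins the vapour, residual nonvolatile mass the floor film. The default
`residue_mode="settle"` applies the diameter cut-off unconditionally; in
practice hygroscopic residue particles equilibrate above it and stay
airborne, settling by Stokes, which is what the `"airborne"` alternative
also enforces for sub-cut-off residues.

The mass audit tracks every boundary flow (released liquid, initial and
supplied vapour, ventilation outflow) against the final inventory; since
every internal transfer is routed explicitly, the ledger closes to
round-off at any step size — the audit measures bookkeeping integrity,
while discretisation accuracy is checked separately through step-halving
convergence of the exposure averages (< 2% change).

## Packaged reference configurations

* **Wall-spray example**: 7.4% w/w aqueous hydrogen peroxide, 150 m³
  room, 8 g/s for 300 s onto 20 m², hollow-cone nozzle (250 µm MMD,
  GSD 1.8, 5 classes, 25° full cone, 0.4 m to the wall, v0 = 12.7 m/s),
  ventilation 0.125 m³/s, 5 h window, floor evaporation restricted to ¾
  of the floor. Substance properties from the published table; activity
  models default to ideal (the published nonideal curves for this pair
  are not tabulated; mildly nonideal behaviour can be supplied as
  polynomial or tabulated `γ(x)` models). The liquid molar volume of
  hydrogen peroxide (not tabulated in the source) uses the standard pure
  density 1450 kg/m³.
* **Room-spray evaluation set**: 19 controlled experiments in a
  11.2 × 4.5 × 4.0 m storage room; aqueous 0.2% dysprosium acetate + 1%
  NaCl, 4 × 1 min spraying with 1 min pauses, 30 min follow-up, with
  measured 37-min TWAs of the nonvolatile aerosol (Respicon) and water
  vapour (hygrometer). The two solutes are pooled into one nonvolatile
  pseudo-component (1.2% w/w, mass-weighted molar mass and volume; the
  dysprosium acetate density is an estimate — it only affects the dry
  size of the residue, weakly). Choices where the source experiments are
  underdocumented, exposed as overrides: ventilation 0 (sealed storage
  room), `N_c = 5`, `dt = 0.05 s` (within the range stated for the
  original simulations), water `beta = 2.4e-3 m/s`, and droplet surface
  temperature equal to room temperature — the measured aerosol is the
  nonvolatile residue, which spends nearly all of its airborne lifetime
  at thermal equilibrium; a psychrometric wet-bulb estimate is available
  via `droplet_cooling=True`. Initial water vapour follows from the
  recorded relative humidity via the Magnus helper at standard pressure.

The synthetic `toy_*` scenarios isolate single mechanisms (one pulse, one
class, selectable volatility/gravity/ventilation) for the analytic
oracles: exponential ventilation decay, the closed-form d²-law droplet
lifetime, film depletion times.

## What the tests show — and what they do not

The suite verifies the mechanisms against independent oracles (closed
forms, mole-balance finite differences, brute-force scans, fine-step
integrations) and the packaged evaluation set reproduces the published
vapour statistics (bias 0.14, relative bias 15.5%, r 0.904) exactly,
because those are properties of the shipped data. Simulating the 19
experiments end-to-end reproduces the measured exposure *ranking*
(Spearman > 0.9 for both aerosol and vapour) and tracks the reference
estimates closely; absolute per-experiment agreement depends on inputs
the experiment reports do not fix (true air exchange, droplet cooling,
size-class count), so it is a plausibility check, not a calibration.
Passing tests demonstrate internal consistency and agreement with this
one evaluation data set — not validity for rooms, spectra or mixtures far
outside it.

## Known limitations

* Uncorrected Stokes settling above ~50 µm overestimates deposition of
  coarse sprays.
* The well-mixed assumption ignores near-field peaks around the sprayer.
* No condensation onto surfaces: in humid, cooling rooms the vapour
  estimate is conservative (high).
* The impaction module covers wall spraying only (not floor-directed
  spraying), with a binary step transfer efficiency.
* Explicit Euler accuracy is first order; exposure averages at the
  default steps are converged to ~1–2%, but individual rate time series
  can show bounded step-to-step oscillation when droplets hover at
  equilibrium with the room air.
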