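# Methods

## Scope and model structure

`zoometals` is a desk-scale tool for studying how microzooplankton
recycling of five trace metals (Fe, Zn, Cu, Co, Mn) responds to four
drivers — stoichiometric food quality, prey quantity, temperature and
zooplankton biomass — and for attributing the variance of recycling fluxes
and their metal:C stoichiometry to those drivers under climate-change
scenarios.  The physical setting is a single well-mixed surface box (the
upper ~100 m) exchanging with a fixed deep reservoir; there is no spatial
grid.  Regional structure, where needed, is emulated by ensembles of boxes
("members as regions").

State variables: one dissolved macronutrient (nitrogen currency, coupled
to carbon by a fixed C:N of 122/16), five dissolved metals, two
phytoplankton groups (nanophytoplankton and diatoms) with Droop-type
variable internal metal quotas capped at `q_max`, one microzooplankton
pool with *fixed* metal:C stoichiometry, and particulate organic carbon
and metal.  Units: concentrations mol m⁻³, quotas mol:mol (absolute, e.g.
80e-6), rates d⁻¹, fluxes mol m⁻³ d⁻¹, time in days with 365-day years.

## Process formulations

* **Growth** `mu = mu_max · Q10^((T-20)/10) · min(N limitation, Fe
  limitation)`, where the Fe limitation is a Droop factor
  `clamp((q_Fe - q_min)/(q_max - q_min), 0, 1)`.  Only iron limits growth;
  the other metals are tracked but non-limiting, which reflects their role
  as recycled tracers rather than growth currencies in this model.
* **Metal uptake** `v = v_max · d/(d + k) · (1 - q/q_max)`, so quotas obey
  `dq/dt = v - mu·q`: slow-growing cells accumulate metal toward `q_max`
  (the mechanism that raises phytoplankton stoichiometry when
  macronutrient stress slows carbon growth).
* **Grazing** multi-prey Michaelis–Menten over nanophytoplankton, diatoms
  and particles with fixed preferences, scaled by the same Q10 factor.
* **Zooplankton budget** per element: with ingested carbon `I_C` and metal
  `I_M`, gross metal assimilation is `min(AE(FQ)·I_M, ae_c·I_C·q_zoo)` —
  efficiency-limited or demand-capped, whichever binds.  The unassimilated
  remainder is split `sigma_diss : (1 - sigma_diss)` between dissolved
  excretion (the recycling flux) and particulate egestion.  `AE(FQ) =
  ae_max · min(FQ, 1/FQ)^ae_shape` is maximal for a balanced diet and
  symmetric in log food quality; the exponent is configurable because only
  the qualitative decline away from 1 is constrained by theory, and
  `ae_shape = 0` deliberately disconnects AE from food quality (used to
  verify counterfactual isolation).
* **Fixed zooplankton stoichiometry.** When assimilation falls short of
  the demand `ae_c·I_C·q_zoo`, the shortfall is drawn from the dissolved
  metal pool (direct uptake by the grazer), falling back to clawing back
  excretion and egestion only if the pool cannot supply it within a step.
  This choice keeps the body quota exactly fixed, keeps every budget
  closed, and — crucially — preserves the defining qualitative law of the
  model, that *net recycling increases as assimilation efficiency drops*.
  Routing the shortfall through the excretion flux instead would invert
  that law (whatever low AE fails to assimilate would be exactly clawed
  back out of the recycling term), making the food-quality counterfactual
  direction unobtainable in principle.
* **Closure and losses**: quadratic zooplankton mortality `m_z·z²` (split
  `sigma_diss` dissolved / rest particulate at the fixed quota), linear
  phytoplankton mortality to detritus, particle sinking (export) and
  remineralisation, linear mixing `kappa(t)·(X_deep - X)` for dissolved
  pools, constant external sources.

## Numerics

Fixed-step RK4, default `dt = 0.25 d`.  Positivity is enforced by
conservative clipping: within each stage, each pool's total outflow is
rescaled so it cannot exceed pool/dt; because rescaling happens at the
source before routing, it never breaks conservation.  Budget accumulators
(per element and for carbon) are integrated by the same RK4 stages, so the
closure check `Δinventory = ∫(sources + mixing - export)` holds to
round-off (~1e-13 relative over a century) on any trajectory, including
branched and concatenated scenario runs.  Instabilities (NaN or
significantly negative pools) abort with the pool and time named.

Convergence order is verified on a deliberately smooth configuration
(single active phytoplankton group, dissolved pools far from depletion,
quotas mid-range) because the full model contains non-smooth elements —
the limiter, the `min` in growth limitation and the assimilation cap —
whose branch crossings locally degrade the observable order even though
each branch is integrated at fourth order.

## Scenarios and the counterfactual

Model year *y* maps to calendar year 1800 + *y*; runs span 1801–2100 after
a 20-year discarded spin-up.  The control keeps seasonal forcing constant;
the climate run branches from the control state in 1851 (bit-identical
before the branch) and applies two monotone ramps to 2100: warming
`delta_t` (default +4 °C) and fractional mixing reduction `delta_kappa`
(default 0.4) — a two-knob summary of the warming / stratification /
reduced-nutrient-supply response of high-emission earth-system
projections.  An optional seasonal mixing cycle peaks a quarter-year
before the temperature maximum.  Analysis windows: PI_REF 1801–1900
(includes the initial transient after spin-up), PRESENT 1991–2000, FUTURE
2091–2100.

The fixed-food-quality counterfactual repeats the climate run with the
per-element food quality *entering the AE function* frozen at its PI_REF
time-mean from the control run; biomass, prey quantity and temperature
evolve freely.  With `ae_shape = 0` the counterfactual is bit-identical to
the climate run, which verifies that freezing touches nothing else.

## Attribution

Responses (per-element recycling flux, or recycling stoichiometry) are
fitted by ordinary least squares with identity link on the four drivers,
per (region, element, response kind, period) group; samples are monthly
means.  Variance shares use the LMG relative-importance decomposition,
computed by the subset-weighted formula
`share_j = Σ_{S⊆others} |S|!(p-1-|S|)!/p! · (R²(S∪{j}) - R²(S))` from the
centred (internally standardised) moment matrix, and checked against an
independent oracle that enumerates all 4! orderings with per-subset
least-squares fits (agreement ≤ 1e-12).  Shares are non-negative, sum to
R², and are invariant to affine rescaling of any column.  For display, the
three biotic shares are renormalised to ternary coordinates (food quality,
prey quantity, zooplankton biomass at the corners), temperature is carried
separately as an absolute variance fraction, groups with R² ≤ 0.5 are
flagged out of the ternary output (but still reported), dominance ties
break by the fixed order qual > quant > zoo and are flagged.

## Synthetic panels

`generate_driver_panel` draws the statistical model the attribution
assumes: four jointly Gaussian drivers per region (stationary AR(1) in
time, since monthly geophysical series are autocorrelated), linear
response, iid Gaussian noise scaled to a target population R².
`population_shares` computes the *exact* population R² and LMG shares from
the pooled (mixture) second moments, giving oracle targets with no
sampling.  An optional exponential back-transform produces lognormal
drivers while the response stays linear in the Gaussian scale, to exercise
the misspecification path.  What these panels do **not** emulate: skewed
or heteroscedastic noise, driver nonlinearity, regime shifts — recovery
results on them bound estimation error under the model's own assumptions,
not real-data robustness.

## Constructed experiments

The dominance sweeps (`experiments.dominance_ensemble`) are deterministic
designed parameter sweeps, not random ensembles, because their purpose is
a direction test with a known answer:

* **zoo sweep** — members vary only the two zooplankton regulation
  parameters, anti-paired (grazing capacity rising 2.0→3.0 d⁻¹ while the
  closure coefficient falls 1600→400) to spread equilibrium zooplankton
  biomass as widely as the stable range allows.  Every pooled
  recycling-flux fit should be dominated by zooplankton biomass.
* **sst sweep** — members vary only the base temperature (12–24 °C).  In a
  closed food web at equilibrium, temperature reaching the recycling of a
  *non-limiting* metal is genuinely mediated by zooplankton biomass, the
  proximate driver, so the pooled fits for those metals split the
  temperature signal between collinear drivers.  Only the growth-limiting
  micronutrient (iron, via its Droop feedback: warming dilutes the iron
  quota, which throttles growth and reshapes iron recycling beyond what
  biomass explains) carries a direct temperature signature; the sweep
  therefore targets iron.  This is a real property of closed equilibrium
  boxes, not an implementation artefact, and is the reason temperature
  attribution in such systems concentrates on the limiting element.

The food-quality drift setup (`experiments.fq_drift_setup`) makes the
food-quality channel active and monotone: an iron-hungry grazer
(`q_zoo(Fe) = 25e-6`) in an iron-poor box supplied only by mixing, with the
macronutrient held replete by a constant external source, under a
stratification-only scenario (mixing −70% by 2100).  Iron food quality
starts near 1.19 and rises monotonically; the assimilation efficiency is
binding throughout, so the counterfactual (frozen at the preindustrial
food quality) recycles strictly less iron per unit carbon than the
reference in every year after the drift onset (1856; the first five years
after the 1851 branch are within integrator noise of the control).

## Default parameters worth knowing

| parameter | default | why |
|---|---|---|
| max quotas (mol:mol) | Fe 80e-6; Zn 40e-6 (nano) / 123e-6 (diatom); Cu 16e-6; Co 1.2e-6; Mn 8e-6 | observational syntheses used by global trace-metal ecosystem models |
| zoo quotas (mol:mol) | Fe, Zn, Cu 10e-6; Co 0.16e-6; Mn 1e-6 | same observational basis; fixed (homeostatic grazer) |
| `ae_max`, `ae_shape` | 0.8, 1 | maximal efficiency at balanced diet; linear decline in min(FQ, 1/FQ) |
| `ae_c`, `sigma_diss` | 0.6, 0.5 | carbon growth efficiency; even dissolved/particulate split of egesta (both pathways real, split unconstrained) |
| `mu_max` | 1.0, 1.4 d⁻¹ | nano vs diatom growth contrast |
| diatom Fe uptake factor | 0.4 × (3·mu_max·q_max) | lower surface:volume of large cells; makes diatoms iron-stressed while nano are grazer-controlled, which is what lets both groups coexist in a single box |
| `g_max`, `k_g` | 2.5 d⁻¹, 2e-3 mol C m⁻³ | microzooplankton grazing scale |
| `m_z` | 800 (mol C m⁻³)⁻¹ d⁻¹ | quadratic closure keeping zoo ~1e-3 mol C m⁻³ |
| `kappa0`, `n_deep` | 0.02 d⁻¹, 4e-3 mol N m⁻³ | ~50-day mixing timescale; deep nitrate ~4 µM equivalent |
| `fe_q_min` | 4e-6 | Droop floor (5% of q_max) required for iron limitation to operate |
| forcing | 18 °C base, ±2 °C season | mid-latitude surface box |
| `dt`, save interval | 0.25 d, 5 d | stability with margin for the fastest (metal-uptake) mode; monthly aggregation downstream |

Problem sizes used by the test-suite and the acceptance script — century
runs at dt = 0.25 d, 8-member sweeps, 50 statistical replicates at
n = 20,000 — were chosen as the smallest sizes at which the measured
quantities are stable to well within their tolerances.

## Known limitations

* One box: no spatial covariance, no advection, no light cycle; "regions"
  are ensemble members, so regional share values of any real ocean are out
  of reach by construction.
* The equilibrium character of the box makes all drivers smooth functions
  of the forcing; deterministic panels therefore have R² ≈ 1 and LMG
  shares split across collinear drivers more evenly than noisy
  observational panels would.
* Zooplankton metal limitation does not feed back on growth; the fixed
  quota is maintained by dissolved uptake instead (see above).
* Mesozooplankton, ligand chemistry, scavenging, oxygen-dependent
  sediment sources, and variable C:N:P are all outside scope.
* The AE(FQ) functional form is a stated stand-in behind a single
  operation; swapping it changes only `assimilation_efficiency` and its
  kernel mirror.
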