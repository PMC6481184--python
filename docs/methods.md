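# Methods

## Model

The package implements the classical pump-leak description of monovalent
ion and water homeostasis in a single animal cell suspended in an
effectively infinite bath. The cell is a well-mixed compartment; membrane
transport is lumped into five pathways per ion — electroconductive
channels, the Na⁺/K⁺ pump, and the NC (Na-Cl), KC (K-Cl) and NKCC
(Na-K-2Cl) electroneutral cotransporters — each characterized by a single
integral rate coefficient. No assumptions are made about the molecular
identity or multiplicity of the underlying transporters: pathways are
distinguished only by the driving forces they respond to, which is what
makes the inverse problem (inferring coefficient changes from concentration
time courses) well posed enough to be useful.

Channel fluxes follow the constant-field (GHK) form. For a cation,
`J = p·u·(cᵢeᵘ − cₒ)/(1 − eᵘ)` (inward positive); for the anion Cl⁻ the
valence −1 form `J = p·u·(cᵢ − cₒeᵘ)/(1 − eᵘ)` is used. At `|u| < 1e−6`
both switch to the analytic limit `p·(cₒ − cᵢ)` to avoid the 0/0 form; the
discarded terms are first order in `u` and negligible at that threshold.
The pump extrudes Na⁺ at `β·[Na]ᵢ` and imports K⁺ at `β·[Na]ᵢ/γ`;
`γ = 1.5` throughout. Cotransport fluxes are proportional to differences
of substrate-concentration products (e.g. `i_NC·([Na]ₒ[Cl]ₒ −
[Na]ᵢ[Cl]ᵢ)`) and carry zero net charge by construction. RT/F is fixed at
26.7 mV (37 °C) and is not temperature-parameterized.

Two constraints close the system:

* **Electroneutrality.** The membrane potential is treated as
  instantaneous (zero-capacitance formulation, as in the red-cell modeling
  lineage this model belongs to): at every step `u` is re-solved from
  `Φ(u) = J_chan,Na + J_chan,K − J_chan,Cl − β[Na]ᵢ(1 − 1/γ) = 0`.
  Capacitive transients relax on the millisecond scale and are far below
  the minute-scale resolution of interest.
* **Osmotic balance.** The cell is taken as perfectly distensible:
  `V = (Naᵢ + Kᵢ + Clᵢ + A) / (kv·([Na]ₒ+[K]ₒ+[Cl]ₒ+B₀))`.

The impermeant-osmolyte pair is derived from the initial state —
`A/V = osmolarity − ([Na]ᵢ+[K]ᵢ+[Cl]ᵢ)` and `z = ([Cl]ᵢ−[Na]ᵢ−[K]ᵢ)/(A/V)`
— and then frozen for the whole run, including apoptosis runs. This is a
documented approximation: measured impermeant-anion content changes only
~3 % over the 4-h apoptotic time course being modeled, while the permeant
ions change by tens of percent.

## Numerics

* **Integration.** Fixed-step explicit Euler on the three ion *contents*,
  default `dt = 0.01` min, with `u` re-solved and the volume re-imposed
  each step, so every accepted state satisfies both constraints
  (electroneutrality to < 1e−6 mM, osmotic balance to < 1e−9 mM). The
  dynamics are minute-scale and non-stiff at published parameter values;
  the test suite includes a step-halving check (endpoints move < 0.01 mM
  between `dt` 0.01 and 0.005). `dt` is exposed on every scenario.
* **Potential solve.** `Φ(u)` is bracketed on `u ∈ [−8, 2]` (about −214 to
  +53 mV) — warm-started from the previous step's root with a progressively
  widened local bracket — and polished by Brent's method to `1e−12` in `u`.
  Monotonicity of `Φ` is not assumed; if no sign change exists in the
  bracket (e.g. no channel permeability while the pump carries charge) an
  explicit error reports the endpoint values. A membrane with no channels
  and no charge-carrying pump has an indeterminate potential that does not
  affect the dynamics; it is reported as NaN rather than invented.
* **Schedules.** Parameter changes are stepwise, applied exactly at their
  event times (integration steps are cut to land on them; no look-ahead).
  The pump decay `β(t) = max(0, β₀ − k_b·t)` uses absolute run time; `k_b`
  is in β-units per minute. Output sampling is every `hp`-th internal step
  plus all event times and the endpoint. Concentration derivatives
  (`prna, prk, prcl`) are backward differences across the last internal
  step; the t = 0 row reports zeros by convention, and balanced-state
  detection therefore skips it.
* **Degenerate inputs.** Negative concentrations after a step raise a
  step-size error rather than propagating; an interior osmolarity
  exceeding the bath's makes the impermeant derivation fail loudly; OSOR
  with zero ouabain-resistant influx is signalled as undefined, never
  returned as infinity.

## Parameter identification

The fitter formalizes what is in practice a trial-and-error procedure:
candidate parameter vectors (base coefficients and/or scheduled overrides,
named `pk` or `pk@60`) are simulated and scored by the sum of squared
concentration residuals over observed (t, Na, K, Cl) points, interpolated
linearly in time. The objective surface is known to be poorly conditioned
— different coefficients dominate in different regimes — so the optimizer
is a derivative-free Nelder-Mead simplex in bound-scaled coordinates, and
no gradient-based convergence guarantee is claimed. Candidates whose
simulated OSOR at the final time falls below a user-supplied floor
`osor_min` are rejected (penalized during the search, excluded from the
result); no default floor is hard-coded because "unacceptably low" is an
experimental judgement that depends on the measured OSOR. If every
candidate is rejected the result says so explicitly.

The synthetic-observation generator samples a simulated trajectory at
stated times and adds independent Gaussian noise per ion and time point
(deterministic for a fixed seed). It emulates concentration measurements
with homoscedastic error; it does **not** emulate per-protein content
normalization error, inter-culture variability, or timing jitter, so
recovery tests bound estimator behaviour under idealized noise only.
Recovery on noiseless self-generated data is exact to the optimizer
tolerance (pk and pcl within 2 %). Under 2 mM noise, identifiability of
`pcl` depends strongly on the sampling design: its driving force (Δμ_Cl)
decays within ~30 min of a permeability step, so the packaged recovery
test samples that transient every 2 min; even then single noise
realizations can land on a shallow likelihood ridge (the global SSE
minimum genuinely off truth), so typical accuracy is asserted as a median
over fixed seeds rather than per-realization.

## Packaged scenarios

The fixtures reproduce the published model configurations: a
transition-to-balance run for a high-potential lymphoid cell
(`table2_balance`), its balanced state as a base for single-parameter
perturbations (`fig1_perturbations`), pump-stop runs at three chloride
permeabilities (`fig2_pumpstop`, `fig3_pumpstop_fit`), the
staurosporine-apoptosis schedule with linear pump decay
(`table4_apoptosis`) and the early-apoptosis stepwise permeability shifts
(`table5_shifts`). All use a 310-mosM bath (140 Na / 5.8 K / 116 Cl / 48.2
impermeant non-electrolyte, `kv` = 1). Problem sizes are desk-scale: the
longest runs are 240 min at `dt` = 0.01 (24 000 steps, ~0.5 s each).

## Known limitations

* Single integral coefficients per pathway: no multi-site pump kinetics,
  no per-isoform channel permeabilities, no Ca²⁺/H⁺/HCO₃⁻ handling.
* `A` and `z` frozen at t = 0 (see above).
* The bath is fixed and is not itself checked for charge balance (the
  published media are not charge-balanced as listed).
* Explicit Euler is adequate for the published regimes but will demand
  small steps if driven with permeabilities orders of magnitude above the
  physiological range; the step-size error exists for exactly that case.
* With the pump off and finite pCl no balanced state exists — swelling
  continues indefinitely; the balance detector correctly never fires.
* Whether OSOR's denominator should include cotransporter K⁺ influx when
  KC/NKCC are active is not settled by the published examples (they have
  both at zero); this implementation includes them, which is stated in the
  report output.
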