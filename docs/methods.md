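# Methods

This note documents the models implemented in `co2perm`, the default
parameter values and why they were chosen, the numerical choices, what
the synthetic-data generators do and do not emulate, and the known
limitations. Units are fixed at cm, s, mmHg and mM throughout the
package; gas volumes use the CO2 STPD molar volume of 22.26 l/mol.

## Carbonate chemistry backbone

All modules share one description of the CO2/HCO3⁻ system: the first
apparent dissociation constant K1′ = [H⁺][HCO3⁻]/[CO2], default
pK1′ = 6.07, so that the bicarbonate-to-CO2 ratio R = 10^(pH−pK1′) is
~17 at pH 7.3 and ~21 at pH 7.4. The uncatalysed hydration rate constant
defaults to k_h = 0.131 s⁻¹, chosen so that the net hydration reaction
at clamped pH 7.3 and 37 °C relaxes with a half-time of 5 s
(ln 2 / [k_h·(1+1/R)]). Carbonic anhydrase (CA) activity A multiplies
*both* the hydration and dehydration rate constants by (A+1), so A = 0
is the uncatalysed solution and no equilibrium is shifted by CA; this is
verified by a test that equilibrates a closed box from the same initial
state with A = 0 and A = 10⁴ and finds identical fixed points.

## Closed-form resistance calculations

Permeability from the solubility-diffusion mechanism, P = D_M·K_P/d;
partition scaling P_gas = P_ref·K_gas/K_ref (which assumes equal
intramembrane diffusivities); series resistance chains
R = Σ d_i/D_i + Σ 1/P_j with apparent permeability 1/R (infinite
permeability is the sentinel `math.inf`, so its resistance contribution
is exactly zero); the plane-sheet cell release rate
(d/D + 1/P)⁻¹·α·Δp/d, converted to ml gas/min with tissue density taken
as 1 g/cm³; and its exact inverse for the required gradient.

**Effective solubility.** For a closed, buffered volume stepped from
pCO2 = p1 to p2, the equilibrium is found by solving the proton balance
(HCO3⁻ formed = protons absorbed by the buffer plus the free-H⁺ change)
for the final pH by bracketed root finding in pH ∈ [2, 12];
α′ = α + Δ[HCO3⁻]·V_m/(p2−p1). The worked 25 mM HEPES example needs a
starting pH and a pKa that the source calculation left unstated;
defaults pH 7.4 and pKa 7.5 give α′ = 51.7·10⁻⁴ cm³/cm³/mmHg against
the quoted 53·10⁻⁴ (3% apart), and both parameters are exposed. An
independent dense-grid scan of the same proton balance is used as the
test oracle.

**Sphere uptake.** The criterion D′·t/r² = 0.6 for ~95% completion is
implemented with the printed coefficient 0.6. Note that the classical
constant-surface-concentration series solution for a sphere puts ~95%
completion nearer D′·t/r² ≈ 0.25; the 0.6 coefficient corresponds to a
more conservative boundary treatment and is kept as printed rather than
re-derived, since the quantity is an order-of-magnitude argument (the
conclusion — microsecond-to-millisecond uptake — is insensitive to it).

## Monolayer reaction-diffusion model

Geometry: back unstirred layer (130 µm) | cell layer (10 µm) | front
unstirred layer (130 µm), each divided into 50 volume elements (all
configurable). The cell-layer thickness is not part of the published
configuration; 10 µm is the standard estimate for an MDCK monolayer.
The back-layer thickness mirrors the front (symmetric chamber).

Species per element: [CO2], [HCO3⁻], and a proton load
x = [H⁺] + [HA] (free plus buffer-bound protons). The monoprotic buffer
(HEPES, 25 mM, pKa 7.5) equilibrates instantaneously; free [H⁺] follows
from x by a closed-form quadratic. Protons diffuse both free (D_H) and
carried on the buffer (D_B) — buffer-facilitated proton diffusion.
Electrodiffusive coupling (Nernst-Planck) is not modelled; each species
diffuses with its own coefficient, and CO3²⁻ is omitted (valid below
pH ~8.5). Diffusion coefficients default to standard 25 °C water values:
D_CO2 = 1.8·10⁻⁵, D_HCO3 = 1.1·10⁻⁵, D_H = 9·10⁻⁵, D_B = 5·10⁻⁶ cm²/s.

Membranes: impermeable to HCO3⁻, H⁺ and buffer; CO2 crosses with
P_CO2 = 0.01 cm/s. Outer boundaries are Dirichlet: pH 7.4 both sides,
[HCO3⁻] 50 mM (back, post-step) and 25 mM (front), [CO2] at local
equilibrium. CA profile: A_i in the cell elements, A_e in all
unstirred-layer elements, and an optional surface-bound A_s confined to
the single element adjacent to the membrane (front face by default,
switchable). The three canonical presets are `curve1` (no CA anywhere),
`curve2` (A_i = 800, A_s = 100) and `curve3` (A_i = 800, A_e = 10,000).

Steady state is obtained by stiff BDF integration (rtol 1e-7, atol
1e-10, sparse Jacobian pattern) over a 2000 s horizon followed by a
200 s confirmation chunk that must change no field by more than 1e-7
relative (the slowest physical timescale, uncatalysed HCO3⁻ turnover,
is ~160 s). At the solution the total carbon flux (CO2 + HCO3⁻) is
uniform across all grid interfaces to ~1e-12 relative, and halving the
element size changes fluxes and slopes by <2% (checked on a preset
without surface CA; the surface-CA configuration is grid-dependent *by
definition*, since A_s occupies the one membrane-adjacent element).

Observables: the initial surface-pH slope is the least-squares slope of
pH vs. distance over the first 20% of the front unstirred layer,
excluding the membrane-adjacent element; the true transmembrane flux is
P_CO2·Δ[CO2] across the front membrane; the slope-based estimate is
D_B·BF·slope with the buffer factor BF = ln10·B·K_a·h/(K_a+h)²
evaluated at the bulk pH (a fixed-BF mode for the estimator; the model
itself always uses the local buffer curve).

**Known limitation — the published flux table.** With the documented
constants the model reproduces the *qualitative* published result
exactly: the surface-pH slope rises ~10-fold from curve1 to curve3
(0.89 → 8.6 pH/cm) while the true flux rises far less
(0.84 → 1.19·10⁻⁶ mmol/cm²/s), so the slope-based estimator
underestimates the flux severely without extracellular CA (est/true
0.08 for curve1 vs 0.51 for curve3). Quantitatively, however, the
published fluxes (2.0–2.5·10⁻⁶ mmol/cm²/s with ≤25% spread) are not
attainable from the published constants: at steady state any 1-D stack
obeys the series bound flux ≤ Δ[CO2]/(Σd_i/D_i + Σ1/P_j), and with two
130 µm unstirred layers, two membranes at 0.01 cm/s and Δ[CO2] ≈ 1.25 mM
that cap is ~0.7–1.0·10⁻⁶ for the no-CA configuration — below the
published 2.0·10⁻⁶ — while uncatalysed hydration at k_h = 0.131 s⁻¹
(reaction length ~115 µm, comparable to the layer) lifts it only
marginally. A ≤25% spread would require uncatalysed interconversion
roughly an order of magnitude faster than k_h. The acceptance checks
for these quantities therefore state the published tolerances and fail
honestly; the corresponding constants (all exposed in
`MonolayerChemistry`) would have to differ substantially from their
documented values to close the gap.

## ¹⁸O-exchange model

State: six concentrations of singly-labelled species — CO2, HCO3⁻ and
H2O in the extracellular and intracellular compartments. The unlabelled
chemistry sits at equilibrium throughout (the experiment runs at
constant pH and total CO2), which makes the labelled system *linear*:

* labelled CO2 hydrates at (A+1)k_h, keeping its label on the HCO3⁻;
* labelled HCO3⁻ dehydrates at specific rate (A+1)k_h/R; the label
  stays on the CO2 with probability 2/3 and is lost to water with
  probability 1/3;
* hydration of unlabelled CO2 by labelled water returns label to HCO3⁻
  at rate (A+1)k_h·[CO2]·w/W (W = 55.5 M);
* membrane fluxes P·a·ΔC couple the compartments, scaled by
  cytocrit/(1−cytocrit) on the extracellular side.

Volume-weighted total labelled oxygen is conserved exactly (the rate
matrix annihilates the volume-weight vector), and the stationary
distribution puts equal labelled fraction on every oxygen site
(2[CO2] : 3[HCO3⁻] : W). Multiply-labelled species are neglected,
valid at tracer enrichment. Intracellular [CO2] equals extracellular
(CO2 equilibrates); intracellular [HCO3⁻] follows pH_i. A reduced
five-state mode holds extracellular labelled water at zero (the pool is
~3000× the carbonate pool); it agrees with the full model to <0.1%.

Because the system is linear with piecewise-constant coefficients, the
primary solver is an eigendecomposition of the 3×3 (solution-only) or
6×6 rate matrix — exact and fast enough to evaluate 40×40 SSQ surfaces
in well under a second. A stiff BDF integration of the same right-hand
side is retained as an independent numerical route (the two agree to
<1e-6 relative), and a molecule-level Monte-Carlo simulation (explicit
labelled molecules, per-event 1/3 loss rule, vectorised event-driven
jumps) matches the ODE within its binomial sampling envelope at 10⁵
molecules.

Trace metrics: half-times are measured relative to the full
(initial − equilibrium) amplitude; the boundary between the fast phase
(dominated by P_CO2 and A_i) and the slow phase (dominated by P_HCO3)
is the earliest time at which the local decay rate of
log(signal − equilibrium) flattens to within a factor 1.5 of the
terminal rate; `terminal_decay_rate` fits the terminal slope over the
5–30% relative-amplitude window, and ln2/rate is the half-time an
observer assigns to the overall decay. With the defaults, the
solution-only decay at pH 7.3 has a terminal half-time of 280 s
(slow eigenvalue of the two-species label subsystem; the rounded
figure-of-merit 3·R ≈ 50 between this decay and the 5 s net-hydration
half-time comes out as 56 here), and raising the red-cell cytocrit from
0.02% to 0.2% accelerates the terminal decay 5.6-fold. The first-order
instrument response (default τ = 3 s, off by default) is applied as the
exact discrete solution of dy/dt = (u−y)/τ.

Fitting minimises Σ(model − trace)² over (log P_CO2, log P_HCO3) with a
deterministic pipeline: an 8×8 log-spaced coarse grid locates the
basin, bounded trust-region least squares refines it; no random numbers
are involved. A flat coarse-grid surface is reported as a fit-quality
warning. On noiseless synthetic red-cell traces the round-trip recovery
error for P_CO2 is <1e-9 cm/s, and the SSQ surface on a 40×40 grid has
a single interior minimum. Sensitivity tables refit the *reference*
trace under a perturbed assumption about one nuisance parameter
(A_i, a, pH_i, pH_e, K1′, P_H2O, ...); because A_i and P_CO2 play
compensating roles in the fast phase, raising the assumed A_i lowers
the fitted P_CO2 (≈ ∓7% per ±5% of A_i for the MDCK-type fixture —
the published magnitudes for this check depend on an unstated cytocrit,
so tests assert sign and order of magnitude).

## Unstirred-layer estimation

1/P_app = 1/P_true + δ/D_CO2, with δ = C·ν across a viscosity series;
ordinary (unweighted) least squares of 1/P_app on ν gives P_true as the
reciprocal intercept, C as the slope, per-point δ, and standard OLS
confidence intervals; a non-positive intercept (negative membrane
resistance) is rejected as physically inconsistent. Viscosities are
accepted in m²/s or cSt. The module is consistent with the resistance
chains by construction: `apparent_from_true(P, δ, D)` equals the series
resistance of one water film (δ, D) plus one membrane (P), exactly.
Only the saline point (0.12 cm/s) and the extrapolated intercept
(0.16 cm/s) of the published red-cell dextran series are printed
anywhere, so the full-series test is a round-trip on synthetic data
generated from the resistance relation.

## Synthetic data

Fixtures carry the literature parameter sets: red cells with
P_CO2 = 0.15 (normal), 0.07 (AQP1-lacking) and 0.01 cm/s
(channel-free), A_i = 20,000, a = 20,000 cm⁻¹, cytocrit 0.02%,
P_HCO3 = 10⁻³ cm/s (upper end of the red-cell anion-exchange range) and
P_H2O = 5·10⁻³ cm/s (diffusional water permeability; the fit is
insensitive to it). MDCK-type cells: P_CO2 = 0.017 (0.0255 with AQP1),
A_i = 500, a = 2,000 cm⁻¹ (10 µm cells), cytocrit 0.8% — chosen so that
cytocrit × A_i = 4, the same chamber-average CA activity as the
red-cell standard condition. Cholesterol-free 150 nm vesicles:
P_CO2 = 0.16 cm/s (the method's upper detection limit), a = 6/d =
4·10⁵ cm⁻¹. Colonic apical membrane: P_CO2 ≈ 0.001 cm/s.

Noise is additive Gaussian on the trace (default σ = 0.5% of the
initial amplitude — the recordings this emulates are smooth, and no
noise model is published), plus an optional linear drift; every
generator is a pure function of (fixture, seed) and replicate seeds are
derived deterministically from the experiment seed. The generator does
not emulate raw ion currents, mass-44/46 ratios, electrode artefacts,
stirring noise, or cell-to-cell heterogeneity — so passing recovery
tests demonstrate identifiability and optimizer correctness under the
stated noise model, not robustness to every artefact of a real
instrument.

## Numerical choices and degenerate inputs

Root finding for pH always brackets in [2, 12] and fails loudly.
Integration tolerances: monolayer BDF rtol 1e-7/atol 1e-10 (tighter
settings can stall the step controller on the surface-CA preset without
changing the solution); label-ODE cross-checks rtol 1e-9. Empty layer
stacks return zero resistance and infinite permeability; zero target
flux returns zero gradient; τ = 0 instrument response is the identity;
non-monotone traces raise metric errors rather than returning numbers.
Equality of bulk conditions on both monolayer faces yields the flat
zero-flux equilibrium regardless of CA activities.

## Limitations

* The monolayer model omits electrodiffusion, CO3²⁻, and any moving-
  electrode artefact; its quantitative mismatch with the published flux
  table is analysed above.
* The ¹⁸O model treats both compartments as well mixed; intracellular
  unstirred layers (relevant for large cells) are outside its scope.
* Instrument response is first order only; the membrane-inlet geometry
  of the spectrometer is not modelled.
* The cholesterol-permeability regression used to motivate fixture
  values is not reimplemented; fixtures carry its end results only.
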