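# Methods

This note records the scientific and numerical choices behind `ventgas`, in
the spirit of a model-description paper: what is computed, under which
assumptions, with which parameters, and where the edges are.

## Thermochemical data

Species free energies come from NASA-7 polynomials (two contiguous ranges,
200–1000–6000 K) evaluated as μ°/RT = H/RT − S/R with the 1 bar ideal-gas
standard state. The packaged table mixes two provenances, recorded per row in
its `source_note` column:

* **GRI-Mech 3.0 transcriptions** for the common combustion species (H, H₂,
  O, O₂, OH, H₂O, C, CH₂, CH₃, CH₄, CO, CO₂, HCO, H₂CO, C₂H₂, C₂H₄, C₂H₆, N,
  N₂, NH, NH₂, NH₃, NO, CN, HCN). Each row's ΔfH°₂₉₈ and S°₂₉₈ were checked
  against standard reference values (agreement within a few kJ/mol and a few
  J/mol/K, i.e. the usual release-to-release spread).
* **Synthetic rigid-rotor/harmonic-oscillator (RRHO) constructions** for CH,
  HNC, C₂, C₃, C₄H₂, C₂N₂, CH₃CN, CH₃NC and HC₃N: statistical-mechanics
  Cp/S/H from published rotational constants, vibrational frequencies,
  electronic degeneracies and ΔfH°₂₉₈, least-squares fitted to NASA-7 form
  with exact anchoring of H(298), S(298) and continuity at the 1000 K seam.
  Cp fit residuals are <1.6% (<3% for C₂, whose low-lying a³Πu state puts a
  bump in Cp). These rows are approximations, not library transcriptions, and
  are labelled synthetic.

Key provenance choices: ΔfH°₂₉₈(HNC) = 194.5 kJ/mol, ΔfH°₂₉₈(CH₃NC) =
163.5 kJ/mol (the measured literature value; it yields
ΔrG(HCN+CH₄→CH₃NC+H₂, 1973 K) = 112.3 kJ/mol, consistent with the ~114 kJ/mol
used in the magmatic-gas literature), ΔfH°₂₉₈(HC₃N) = 354 kJ/mol.

**Cyanoacetylene** has two selectable treatments (`hc3n_mode`): the RRHO table
row, or (default) a mass-action polynomial
lnK(T) = 2.96×10⁵/T − 4.83 lnT − 28.47 + 1.91×10⁻³T − 1.10×10⁻⁷T² for its
assembly from neutral atoms (H + 3C + N → HC₃N, activities in bar), from
which μ°(HC₃N)/RT = μ°(H)/RT + 3μ°(C)/RT + μ°(N)/RT − lnK. The two differ by
a factor ~5 in predicted HC₃N at 2000 K — a fair indication of the data
uncertainty for this species.

## Graphite saturation

Graphite enters only through the saturation vapor pressure of carbon monomer,

    log10 p_vap(bar) = a − b/T − c/T²,

with defaults a=4.855, b=2.5709×10⁴, c=10⁷ ("equilibrium" variant) and
a=6.455, b=2.7709×10⁴, c=10⁷ ("kinetics" variant); both coefficient sets are
config-overridable. The c/T² reading of the quadratic term was chosen because
it gives effective sublimation enthalpies of 684 and 722 kJ/mol — bracketing
the carbon-atom sublimation enthalpy (~717 kJ/mol) — and because the
equilibrium variant then reproduces exp(−ΔfG(C,g)/RT) from standard tables to
~0.01 dex at 2000 K (3×10⁻¹¹ bar), which is exactly the saturation condition a
thermodynamically consistent equilibrium code enforces. The kinetics variant
sits a factor ~4 above the equilibrium one at 1973 K; that gap is what makes
the two model branches diverge at saturation. Because the equations defining
these fits are ambiguous in their source, every coefficient is exposed in
`VaporPressureFit`.

Carbon speciation sensitivity: saturated HC₃N scales as p_vap³ (it carries
three carbon atoms), so a 0.3 dex uncertainty in p_vap is a decade in HC₃N.
This is the dominant systematic in the model: our equilibrium branch puts
saturated HC₃N at 0.096 ppm and the kinetics branch at ~25 ppm at
1700 °C/100 bar, bracketing the ~1 ppm headline of the scenario literature
from below and above.

## Equilibrium solver

Element-potential formulation: p_i = exp(−μ°_i/RT + Σ_e a_ie λ_e), unknowns
λ_e (one per element) and a budget log-scale σ, equations = per-element
conservation in log form plus Σp_i = P. Damped Newton with analytic Jacobian,
step clip 3 log units, backtracking line search, convergence at max-norm
10⁻¹³ of the log residuals (giving element conservation to ≲10⁻¹⁵ relative),
iteration cap 200, up to 5 seeded random restarts (never needed in the test
conditions, but kept for robustness on extreme budgets). The initial guess
solves the least-squares problem that would make all species equally
abundant — crude, but it keeps every exponent finite.

Graphite clamp: solve unconstrained; if p_C > p_vap(T), re-solve with
λ_C = μ°_C/RT + ln p_vap fixed (carbon activity 1), drop the carbon
conservation row, and assign the carbon remainder to the solid. The returned
`graphite_fraction` is the condensed fraction of total carbon and is
continuous (from 0) across the threshold. The saturation threshold itself is
found by bisection in the carbon atom fraction to 10⁻³.

Degenerate budgets (single element) reduce to allotrope partitions and are
supported; the two-species O/O₂ case is tested against its quadratic closed
form, and small systems against an independent dense-grid Gibbs-minimization
oracle.

## Kinetics

Mass-action ODEs in concentrations (cm⁻³) at constant T and volume, stiff BDF
(rtol 10⁻⁸, atol 10⁻²⁰ cm⁻³), logarithmic output sampling (60 points). The
integrator works internally in density-scaled variables (n/n_tot): near
equilibrium the opposing forward/reverse fluxes reach ~10¹⁹ cm⁻³s⁻¹ and their
difference is all cancellation, which destroys finite-difference Jacobians in
raw units.

Reverse rate constants are k₋ = k₊/Kc with Kc = Kp·n°^Δν (n° the 1 bar number
density), so the endpoint is the thermochemical equilibrium whatever the
forward rates. The packaged reduced network (19 species, 17 reversible
reactions) therefore uses *placeholder* modified-Arrhenius forward rates
(k = A (T/300)ⁿ e^(−Ea/T), Ea in Kelvin) chosen only so that relaxation
completes well within one day of model time; absolute timescales are
explicitly not predictions. The network's stoichiometry matrix has rank
n_species − n_elements, so its equilibrium manifold is the full element-
constrained equilibrium, and a one-day integration from the fiducial gas
matches the clamped equilibrium solver species-by-species to <10⁻³ relative.

Gas↔graphite exchange is a single solid reservoir with flux
k_cond·(n_C − n_sat), n_sat = p_vap/(k_B T); with solid present the flux runs
both ways, with the reservoir exhausted only supersaturation condenses, and
the two regimes are switched by integrator events. The magnitude
k_cond = 1/τ with τ = 10⁻⁸ s by default: the saturated monomer concentration
(~10⁸ cm⁻³) is eleven orders below the gas density, so macroscopic carbon
exchange within a day *requires* a fast monomer channel; only the ratio
(which fixes the equilibrium) is physically constrained, and τ is
config-exposed.

## Scenario conventions

* Temperatures are Celsius at user interfaces, Kelvin internally (offset
  273.15). The fiducial state is 1700 °C, 100 bar.
* The fiducial gas is CO 0.35, H₂ 0.10, N₂ 0.057, O₂ 7.6×10⁻¹⁰, CH₄ 1.4×10⁻⁶,
  CO₂ 0.23, H₂O 0.26; the printed row sums to 0.997 and the residual is
  spread proportionally so the state normalizes. Its element budget is
  H 0.722, C 0.582, N 0.114, O 1.073 atoms per molecule.
* `nitrogen_fraction` is the N₂ mole fraction imposed on the base gas
  (default 0.057).
* "Added graphite" is parametrized by the carbon atom fraction of total atoms
  in the budget, holding the other elements' ratios fixed. Two summary
  measures of the saturation point are reported: the atom fraction at which
  the clamp first engages (0.360 for the fiducial gas at 1700 °C/100 bar),
  and the added carbon relative to the base gas's own carbon content (0.848).
  The second is the measure that corresponds to the "~80%" graphite budget
  quoted for this scenario; the first *cannot* reach 0.8 for any CO-dominated
  gas (with O=1.07, H=0.72, N=0.11 per molecule the gas cannot hold more than
  about half of all atoms as carbon even with all hydrogen driven into
  acetylene), which is why we read the quoted value as the second measure.
* Oxygen fugacity: fO₂ = p(O₂); the QFM reference is the Frost (1991)
  parameterization log₁₀fO₂ = −25096.3/T + 8.735 + 0.110(P−1)/T,
  config-replaceable. Only deviations from the buffer are meaningful here;
  note the parameterization is calibrated below ~1500 K and is extrapolated
  at magmatic temperatures (the fiducial gas sits ~2–3 log units below the
  extrapolated buffer rather than the nominal −1).
* CH₃NC is estimator-only: [CH₃NC] = e^(−ΔrG/RT)[HCN][CH₄]/[H₂]. Evaluated
  with ΔrG = 114 kJ/mol, T = 1973 K and the stated input ranges
  ([HCN]=10⁻³–10⁻², [CH₄]=3–7×10⁻³, [H₂]=0.2) this formula yields
  1.4×10⁻⁸–3.4×10⁻⁷ — below the ~1 ppm sometimes quoted for this estimator;
  the formula is implemented literally and the discrepancy documented rather
  than absorbed.

## Synthetic fixtures and what the tests show

All test inputs are generated in-repo: the fiducial gas, log-uniform random
element budgets (PCG64, seeded, bounds 10⁻²–10⁰), and random reversible toy
networks (≤8 species) whose reference equilibria come from an independent
zoomed dense-grid Gibbs minimization over reaction extents. Toy networks are
restricted to mole-conserving reactions (constant pressure at constant
volume) with reaction bases spanning the full composition space, so kinetics
endpoint, element-potential solver, and brute-force oracle must all agree —
the tests verify this to 1%.

These fixtures emulate the *structure* of the problem (stiff abundance
ranges, detailed balance, condensation), not real magmatic gas: passing tests
demonstrate internal consistency of the thermodynamics/kinetics machinery and
agreement with the curated fixture data, not the accuracy of any particular
thermochemical datum. Real-data caveats: thermochemistry provenance moves
minor-species predictions by factors of a few (a decade for HC₃N via the
p_vap³ amplification); the pressure scaling of decompressed cyanoacetylene in
this model is ~1 dex per dex, shallower than the ~2 dex per dex sometimes
quoted.

## Numerical edge cases

* Mixing ratios are validated non-negative and normalized to 10⁻⁹.
* Species absent from the initial kinetic state start at 10⁻³⁰ of the total
  density; the integrator floors concentrations at 0 in the rate evaluation.
* Equilibrium exponents are clipped at ±700 to avoid overflow during early
  Newton steps.
* Out-of-window vapor-pressure evaluations (outside 1000–4500 K) warn and
  extrapolate rather than raise, except in the kinetics exchange-rate
  construction, where they are an error.
* Evaluating a species polynomial outside its fitted range raises an error
  naming the species; range boundaries are inclusive, and the two fitted
  ranges of every packaged species agree at the seam to better than 10⁻³
  relative in μ°/RT.
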