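# ventgas

Thermochemical modelling of nitrogen-rich magmatic gas flowing through
graphite-saturated crust — the geochemical setting proposed as a clean,
high-yield source of prebiotic feedstock molecules on the Hadean Earth.
`ventgas` predicts gas-phase mixing ratios of the nitriles HCN and HC₃N
(cyanoacetylene) and the isonitriles HNC and CH₃NC (methyl isocyanide,
estimated) as functions of added graphite, magma temperature (1300–1800 °C),
pressure (1–1000 bar), and H/C/N/O elemental composition.

It is written for researchers in prebiotic geochemistry and planetary
volcanology who want a small, transparent, fully testable re-implementation of
this class of calculation rather than a large black-box equilibrium code.

## The model

**Thermochemistry.** Every gas species carries NASA-7 polynomial fits from
which Cp/R, H/RT, S/R, and the standard-state chemical potential
μ°/RT = H/RT − S/R are evaluated (ideal gas, activities = partial pressure /
1 bar). The packaged table (`ventgas/data/thermo_hcno.csv`, ~34 H/C/N/O
species) combines transcribed GRI-Mech 3.0 coefficients with
rigid-rotor/harmonic-oscillator fits constructed from spectroscopic constants
for species GRI-Mech lacks (HNC, C₂, C₃, C₄H₂, C₂N₂, CH₃CN, CH₃NC, HC₃N).
Cyanoacetylene can alternatively (and by default) be driven by a dedicated
mass-action polynomial lnK(T) for its assembly from H + 3C + N atoms.

**Equilibrium with graphite.** The solver uses the element-potential
(Lagrange-multiplier) formulation: at equilibrium

    p_i = exp(−μ°_i/RT + Σ_e a_ie λ_e),

with one potential λ_e per element plus a budget scale, solved by damped
Newton iteration in log variables. Graphite condensation is a saturation
clamp: if the carbon-monomer partial pressure would exceed the graphite vapor
pressure p_vap(T) (fit log₁₀p = a − b/T − c/T², separate coefficient sets for
the kinetics-flavoured and equilibrium-flavoured models), the carbon potential
is pinned at carbon activity 1 and the excess carbon condenses.

**Kinetics.** A reversible reaction network (plain-text reaction-list format;
a reduced 19-species / 17-reaction H/C/N/O network ships as a fixture) is
integrated with a stiff BDF solver. Reverse rate constants are derived from
the equilibrium constants, k₋ = k₊/Keq (detailed balance), so the endpoint is
fixed by thermochemistry regardless of the forward-rate choices; graphite is a
zero-dimensional solid reservoir exchanging with gas-phase atomic carbon at
its saturation concentration.

## Worked example

Graphite-saturated equilibrium of the fiducial magmatic gas (QFM−1 volcanic
gas with 5.7% N₂) at 1700 °C and 100 bar:

```
$ ventgas equilibrate --carbon-fraction 0.9 --out out/
saturated=True graphite_fraction=0.9374
  CO     7.1917e-01
  H2     2.3485e-01
  N2     3.7648e-02
  CH4    2.7112e-03
  H2O    2.0662e-03
  HCN    1.7243e-03
  CO2    1.4124e-03
  C2H2   1.7205e-04
```

With carbon held at 90% of all atoms, 93.7% of it condenses as graphite and
the leftover gas is strongly reduced and *purified*: CO and H₂ dominate,
diacetylene (C₄H₂, the tar precursor that plagues graphite-free models) is
down at 2×10⁻⁸, and the prebiotically interesting species reach
HCN ≈ 0.17%, HNC ≈ 0.007%, HC₃N ≈ 0.1 ppm of the gas phase.

The methyl isocyanide estimator uses the isomer-exchange reaction
HCN + CH₄ → CH₃NC + H₂ (ΔrG ≈ 112 kJ/mol at 1700 °C from the packaged table):

```
$ ventgas estimate-ch3nc --hcn 1e-3
3.724195e-08
```

i.e. [CH₃NC] = e^(−ΔrG/RT)·[HCN][CH₄]/[H₂] ≈ 3.7×10⁻⁸ for [HCN]=10⁻³,
[CH₄]=7×10⁻³, [H₂]=0.2.

Other drivers: `ventgas sweep-graphite` (mixing ratios vs added graphite,
equilibrium and kinetics branches), `ventgas sweep-temperature`,
`ventgas sensitivity` (H/C/N/O × T × P grid), `ventgas kinetics-run`
(one day of model time on the reduced network), and `ventgas fixtures`
(emit the packaged or random fixtures). All library functionality is in
`ventgas.thermo`, `ventgas.equilibrium`, `ventgas.kinetics`,
`ventgas.scenarios`, and `ventgas.fixtures`.

## Limitations

Sulfur, phosphorus and metal chemistry are out of scope, as are condensates
other than graphite, magma volatile solubility, photochemistry, and transport.
Absolute kinetic timescales are placeholders; only the kinetics *endpoint*
(which detailed balance pins to the thermochemistry) is meaningful. See
`docs/methods.md` for the model assumptions, parameter choices, and known
discrepancies.
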