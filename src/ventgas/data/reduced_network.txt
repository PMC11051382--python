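# Reduced H/C/N/O reversible network for magmatic-gas kinetics.
# Forward rates are placeholders (order-of-magnitude Arrhenius values chosen so
# the network relaxes well within one day of model time); reverse rates are
# derived from the thermo table at run time, so the equilibrium endpoint is set
# by thermochemistry alone.  A is in cm^3-molecule-s units implied by reaction
# order, Ea in Kelvin.
# species: 19
# reactions: 17
# graphite_exchange: true
H2 <=> H + H ; A=1.0e3 n=0 Ea=10000
O2 <=> O + O ; A=1.0e3 n=0 Ea=10000
O + H2 <=> OH + H ; A=1.0e-11 n=0 Ea=3000
OH + H2 <=> H2O + H ; A=1.0e-11 n=0 Ea=2000
CO2 + H <=> CO + OH ; A=1.0e-11 n=0 Ea=8000
CH4 + H <=> CH3 + H2 ; A=1.0e-11 n=0 Ea=4000
CH3 + H <=> C + 2 H2 ; A=1.0e-11 n=0 Ea=6000
C + O2 <=> CO + O ; A=1.0e-11 n=0 Ea=2000
C + CO2 <=> 2 CO ; A=1.0e-11 n=0 Ea=2000
C + H2O <=> CO + H2 ; A=1.0e-11 n=0 Ea=2000
2 CH3 <=> C2H2 + 2 H2 ; A=1.0e-11 n=0 Ea=4000
2 C2H2 <=> C4H2 + H2 ; A=1.0e-12 n=0 Ea=5000
N2 <=> N + N ; A=1.0e3 n=0 Ea=10000
N + H2 + H <=> NH3 ; A=1.0e-30 n=0 Ea=0
CH3 + N <=> HCN + H2 ; A=1.0e-11 n=0 Ea=1000
HCN <=> HNC ; A=1.0e0 n=0 Ea=5000
C2H2 + HCN <=> HC3N + H2 ; A=1.0e-12 n=0 Ea=4000
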