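# Compound registry: species name -> elemental formula.
# Biomass uses the generic composition CH1.8O0.5N0.2.
galacturonate: C6H10O7
pyruvate: C3H4O3
acetate: C2H4O2
formate: CH2O2
co2: CO2
h2: H2
biomass: CH1.8O0.5N0.2
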