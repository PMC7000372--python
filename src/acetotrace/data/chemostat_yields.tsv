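compound	value	sd	unit
biomass	0.17	0.02	cmol_per_cmol
acetate	0.57	0.03	cmol_per_cmol
formate	0.02	0.01	cmol_per_cmol
co2	0.18	0.02	cmol_per_cmol
h2	0.02	0.01	mol_per_cmol
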