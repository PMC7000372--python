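compound	value	sd	unit
galacturonate	-4.0	0.2	mmol_gx_h
acetate	6.9	0.4	mmol_gx_h
formate	0.4	0.2	mmol_gx_h
co2	4.3	0.3	mmol_gx_h
h2	0.2	0.1	mmol_gx_h
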