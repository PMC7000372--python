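gene_id	protein_function	ec_number	panel	rpkm	rpkm_avgdev
F7O84_RS17360	Uronate isomerase	5.3.1.12	entner_doudoroff	5852	2398
F7O84_RS17370	Tagaturonate reductase	1.1.1.58	entner_doudoroff	3067	1236
F7O84_RS17375	Altronate dehydratase	4.2.1.7	entner_doudoroff	8426	3296
F7O84_RS17390	2-Dehydro-3-deoxygluconokinase	2.7.1.45	entner_doudoroff	3863	1343
F7O84_RS17395	2-Dehydro-3-deoxyphosphogluconate aldolase	4.1.2.14	entner_doudoroff	1752	245
F7O84_RS03200	Pyruvate:ferredoxin oxidoreductase	1.2.7.1	acetate_production	4145	278
F7O84_RS03160	Pyruvate formate lyase	6.2.1.3	acetate_production	1893	651
F7O84_RS05985	Phosphate acetyltransferase	2.3.1.8	acetate_production	1500	176
F7O84_RS05980	Acetate kinase	2.7.2.1	acetate_production	1625	200
F7O84_RS07405	Formate dehydrogenase	1.17.1.9	wood_ljungdahl	14	3
F7O84_RS05385	Formate-tetrahydrofolate ligase	6.3.4.3	wood_ljungdahl	256	58
F7O84_RS05380	Methenyl-THF cyclohydrolase/methylene-THF dehydrogenase	3.5.4.9/1.5.1.5	wood_ljungdahl	236	9
F7O84_RS08335	Methyl-tetrahydrofolate reductase	1.5.1.20	wood_ljungdahl	126	13
F7O84_RS02745	5-Methyl-THF:corrinoid/iron-sulfur protein methyltransferase	2.1.1.258	wood_ljungdahl	144	19
F7O84_RS02405	Prismane/CO dehydrogenase family	1.7.99.1	codh_candidates	40	8
F7O84_RS11645	Prismane/CO dehydrogenase family	1.7.99.1	codh_candidates	315	51
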