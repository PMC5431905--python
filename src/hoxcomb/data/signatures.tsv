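# hoxcomb built-in signature table
# One constraint per line: signature_name<TAB>position<TAB>allowed_residues[<TAB>kind]
# Positions are 1-based analysis-segment coordinates (homeodomain 1-60,
# carboxy flank 61-72). kind is diagnostic_class or lineage_motif
# (default lineage_motif). Lines starting with '#' are comments;
# '#note<TAB>name<TAB>text' attaches a free-text note to a signature.
#note	central_class	Subset: the full central-class diagnostic set has 11 homeodomain positions; only the 8 widely printed ones (Q6, LTR(R/K)RR 26-31, E59) are shipped here. Extend via a user table to add the remaining three.
central_class	6	Q	diagnostic_class
central_class	26	L	diagnostic_class
central_class	27	T	diagnostic_class
central_class	28	R	diagnostic_class
central_class	29	RK	diagnostic_class
central_class	30	R	diagnostic_class
central_class	31	R	diagnostic_class
central_class	59	E	diagnostic_class
posterior_class	3	K	diagnostic_class
posterior_class	14	A	diagnostic_class
posterior_class	18	R	diagnostic_class
posterior_class	20	Y	diagnostic_class
posterior_class	21	V	diagnostic_class
lox5_parapeptide	64	K	lineage_motif
lox5_parapeptide	65	L	lineage_motif
lox5_parapeptide	66	T	lineage_motif
lox5_parapeptide	67	G	lineage_motif
lox5_parapeptide	68	P	lineage_motif
gnathifera_pg6	63	K	lineage_motif
gnathifera_pg6	64	S	lineage_motif
gnathifera_pg6	65	IL	lineage_motif
gnathifera_pg6	66	N	lineage_motif
gnathifera_pg6	67	D	lineage_motif
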