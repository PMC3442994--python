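kind	name	mono_mass	targets
residue	G	57.02146
residue	A	71.03711
residue	S	87.03203
residue	P	97.05276
residue	V	99.06841
residue	T	101.04768
residue	C	103.00919
residue	L	113.08406
residue	I	113.08406
residue	N	114.04293
residue	D	115.02694
residue	Q	128.05858
residue	K	128.09496
residue	E	129.04259
residue	M	131.04049
residue	H	137.05891
residue	F	147.06841
residue	R	156.10111
residue	Y	163.06333
residue	W	186.07931
constant	water	18.010565
constant	proton	1.00728
modification	iTRAQ4plex	144.10206	N-term,K
modification	carbamidomethyl	57.02146	C
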