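# Per-residue physicochemical scales, one row per published index.
# Columns follow the fixed alphabet A C D E F G H I K L M N P Q R S T V W Y.
# Sources (classic literature values):
#   kyte_doolittle_hydropathy  Kyte & Doolittle (1982) J Mol Biol 157:105
#   hopp_woods_hydrophilicity  Hopp & Woods (1981) PNAS 78:3824
#   eisenberg_hydrophobicity   Eisenberg et al. (1984) consensus scale
#   monoisotopic_residue_mass  residue (water-free) monoisotopic masses
#   net_charge_ph7             side-chain formal charge near pH 7 (His 0.1)
#   grantham_polarity          Grantham (1974) Science 185:862
#   zimmerman_bulkiness        Zimmerman et al. (1968) J Theor Biol 21:170
#   chou_fasman_helix          Chou & Fasman (1978) P-alpha propensities
#   chou_fasman_sheet          Chou & Fasman (1978) P-beta propensities
#   isoelectric_point          pI of the free amino acid
property_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
kyte_doolittle_hydropathy	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hopp_woods_hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
eisenberg_hydrophobicity	0.62	0.29	-0.9	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
monoisotopic_residue_mass	71.03711	103.00919	115.02694	129.04259	147.06841	57.02146	137.05891	113.08406	128.09496	113.08406	131.04049	114.04293	97.05276	128.05858	156.10111	87.03203	101.04768	99.06841	186.07931	163.06333
net_charge_ph7	0.0	0.0	-1.0	-1.0	0.0	0.0	0.1	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
grantham_polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
zimmerman_bulkiness	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
chou_fasman_helix	1.42	0.7	1.01	1.51	1.13	0.57	1.0	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
chou_fasman_sheet	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
isoelectric_point	6.0	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.3	5.65	10.76	5.68	5.6	5.96	5.89	5.66
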