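# Curated docking score table: 28 phytochemical ligands docked against the NF-kB p65-RelA
# homodimer (PDB 1NFI). lbe = lowest binding energy in kcal/mol (mean and SD over three
# independent dockings); pki = predicted inhibition constant in uM. Source SDs printed as
# "<0.01" are encoded as their bound 0.01.
name	lbe_mean	lbe_sd	pki_mean	pki_sd	pki_unit	site	pharmacophore
β-Amyrin	-8.70	0.01	0.42	0.01	uM	RHD DNA site	GLU222;ASP223;ILE224;GLU225;PHE239;PRO275
Lupeol	-7.59	0.01	2.72	0.05	uM	RHD DNA site	LYS28;GLU222;ASP223;ILE224;GLU225;PHE239;GLN241;PRO275
β-Sitosterol	-7.53	0.10	3.06	0.47	uM	RHD DNA site	LYS28;GLU222;ASP223;ILE224;GLU225;PHE239;GLN241;PRO275
Luteolin-7-O-glucoside	-6.95	0.03	8.05	0.53	uM	RHD DNA site	LYs28;ARG30;GLU222;ASP223;ILE224;GLU225;GLY237;SER238;PHE239;GLN241;PRO275;SER276
Daucosterol	-6.90	0.11	8.79	1.70	uM	RHD DNA site	HIS181;GLN220;LYS221;GLU222;ALA242;VAL244;ARG246;GLN247
β-Eudesmol	-6.70	0.01	12.23	0.15	uM	RHD DNA site	LYS221;GLU222;ILE224;GLU225;VAL226;ARG236;GLY237;SER238;PHE239;GLN241;PRO275
(−)-Epicatechin	-6.41	0.04	20.01	1.40	uM	RHD DNA site	GLU222;ASP223;ILE224;GLU225;PHE239;PRO275
Myricetin	-6.32	0.17	23.87	7.32	uM	RHD DNA site	THR71;ARG73;GLU101;ASN139;PRO140;GLN142;GLN162;VAL163;THR164;PRO177
(+)-Catechin	-6.28	0.02	25.16	0.95	uM	RHD DNA site	GLN29;VAL219;GLN220;LYS221;VAL224;ARG246;GLN247
Quercetin hydrate	-6.15	0.01	31.17	0.19	uM	RHD DNA site	VAL219;GLN220;LYS221;VAL244;ARG246;GLN247
Luteolin	-6.14	0.02	32.14	0.15	uM	RHD DNA site	HIS181;GLN220;LYS221;GLU222;HIS245;ARG246
Kaempferol	-6.10	0.01	34.24	0.70	uM	RHD DNA site	VAL219;GLN220;LYS221;VAL244;ARG246;GLN247
Bisabelol oxide B	-6.03	0.01	38.18	0.21	uM	RHD DNA site	GLN220;LYS221;VAL244;HIS245;ARG246;GLN247
Chlorogenic acid	-6.01	0.12	39.73	7.82	uM	RHD DNA site	GLN29;PHE184;LYS218;VAL219;GLN220;LYS221;VAL244;GLN247
Apigenin	-5.91	0.00	46.78	0.12	uM	RHD DNA site	GLN29;GLN220;LYS221;GLU222;VAL244;HIS245;ARG246;GLN247
A-Bisabolol	-5.85	0.03	51.77	2.68	uM	RHD DNA site	GLU222;ASP223;ILE224;GLU225;VAL226;ARG236;GLY237;SER238;PHE239;GLN241;PRO275
Guaiazulene	-5.75	0.01	61.15	0.10	uM	RHD DNA site	GLU222;ILE224;GLU225;VAL226;ARG236;GLY237;PHE239;SER240;GLN241;PRO275
Quercitrin	-5.66	0.06	70.71	7.19	uM	RHD DNA site	VAL219;GLN220;LYS221;GLU222;VAL244;ARG246;GLN247
Caffeic acid	-5.64	0.05	73.56	5.42	uM	RHD DNA site	VAL219;GLN220;LYS221;GLU222;VAL244;ARG246;GLN247
Bisabolol oxide A	-5.37	0.01	116.55	0.01	uM	RHD DNA site	VAL219;GLN220;LYS221;ALA242;VAL244;HIS245;ARG246;GLN247
Chamazulene	-5.32	0.01	126.69	0.26	uM	RHD DNA site	GLU222;ASP223;ILE224;ARG236;PHE239;SER240;GLN241;PRO275
Bisabolone oxide A	-5.12	0.01	175.23	0.16	uM	RHD DNA site	GLU222;ASP223;ILE224;GLU225;VAL226;ARG236;GLY237;SER238;PHE239;PRO275
Syringic acid	-4.96	0.01	232.16	2.85	uM	RHD DNA site	ILE23;ILE24;GLU25;GLN26;GLU49;ARG50;LYS221;GLU222
Farnesol	-4.68	0.02	374.02	10.22	uM	RHD DNA site	GLN29;GL220;LYS221;GLU222;ALA242;VAL244;ARG246;GLN247
Gentisic acid	-4.48	0.01	518.79	9.09	uM	RHD DNA site	ILE24;GLU25;GLN26;ARG50;LYS221;GLU222
(+)-Terpinen-4-ol	-4.14	0.01	925.85	10.48	uM	RHD DNA site	VAL219;GLN220;LYS221;GLU222;VAL244;GLN247
P-Cymene	-4.14	0.01	929.21	0.34	uM	RHD DNA site	LYS221;ILE224;GLU225;ARG236;GLY237;PHE239;GLN241
Citronellol	-4.10	0.01	990.93	1.02	uM	RHD DNA site	LYS221;GLU222;ILE224;GLU225;VAL226;ARG236;GLY237;SER238;PHE239;GLN241
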