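# Curated docking score table: lupeol and quercetin plus the three site-defining control
# drugs docked against alpha/beta-tubulin (PDB 5N5N), one row per ligand/grid-box pair.
# pki here is in mM. Source SDs printed as "<0.01" are encoded as 0.01.
name	lbe_mean	lbe_sd	pki_mean	pki_sd	pki_unit	site	pharmacophore
Colchicine	-7.01	0.14	0.007	0.01	mM	colchicine grid box	α:LEU248;α:LYS254;α:LYS352;β:GLN11;β:ASN101;β:GLY142;β:GLY143;β:GLY144;β:THR145;β:GLU183;β:ASN206;β:TYR224
Lupeol (colchicine site)	-4.48	0.08	0.520	0.07	mM	colchicine grid box	α:LEU248;α:LYS254;α:LYS352;β:GLN11;β:GLU71;β:ASP98;β:ALA99;β:ALA100;β:ASN101;β:GLY142;β:GLY143;β:GLY144;β:THR145;β:THR179;β:GLU183
Quercetin (colchicine site)	-4.72	0.15	0.352	0.08	mM	colchicine grid box	α:GLN247;α:LEU248;α:LYS254;α:LYS352;β:GLN11;β:ALA12;β:ASP69;β:GLU71;β:ALA99;β:ALA100;β:ASN101;β:GLY144;β:THR145;β:THR179;β:ALA180
Paclitaxel	-7.37	0.25	0.004	0.01	mM	paclitaxel grid box	α:LEU217;α:HIS229;α:LEU230;α:ALA233;α:SER236;α:PHE272;α:ALA273;α:PRO274;α:LEU275;α:THR276;α:SER277;α:ARG278;α:ARG320;α:PRO360;α:ARG369;α:LEU371
Lupeol (paclitaxel site)	-7.12	0.01	0.006	0.01	mM	paclitaxel grid box	α:THR276;α:GLN281;α:ARG284;α:LEU286;α:LEU371;α:LYS372
Quercetin (paclitaxel site)	-5.99	0.29	0.045	0.02	mM	paclitaxel grid box	α:LEU217;α:PRO274;α:LEU275;α:THR276;α:SER277;α:ARG278;α:GLN281;α:LEU286;α:LEU371;α:LYS372
Vincristine	-8.42	0.15	0.001	0.01	mM	vincristine grid box	α:GLN11;α:CYS12;α:GLN15;α:ASN101;α:SER140;α:GLY142;α:GLY143;α:VAL172;α:PRO173;α:SER174;α:ASP179;α:THR180;α:ASN206;α:TYR224;α:ASN228
Lupeol (vincristine site)	-8.62	0.04	0.001	0.01	mM	vincristine grid box	α:GLY10;α:GLY11;α:SER140;α:GLY142;α:GLY143;α:VAL171;α:VAL172;α:PRO173;α:SER174;α:VAL177;α:ASP179;α:GLU183;α:ASN206;α:TYR210;α:TYR224
Quercetin (vincristine site)	-6.77	0.06	0.011	0.01	mM	vincristine grid box	α:CYS12;α:GLN15;α:GLY142;α:VAL172;α:PRO173;α:SER174;α:VAL177;α:ASP179;α:GLU183;α:ASN206;α:GLU207
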