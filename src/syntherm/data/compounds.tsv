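# Standard formation Gibbs energies and enthalpies at 298.15 K, I = 0, kJ/mol.
# Aqueous solutes and water follow Alberty (2003); species absent there follow
# Amend & Shock (2001) / Shock (1995) compilations (source tag AmendShock).
# A blank dfH0 means no vetted enthalpy is bundled; operations that need it
# raise instead of assuming zero.
identifier	formula	charge	phase	dfG0	dfH0	source
H2	H2	0	gas	0.0	0.0	Alberty
CO	CO	0	gas	-137.17	-110.53	Alberty
CO2	CO2	0	gas	-394.36	-393.50	Alberty
CH4	CH4	0	gas	-50.72	-74.81	Alberty
N2	N2	0	gas	0.0	0.0	Alberty
CO2(aq)	CO2	0	aqueous-solute	-385.98	-413.80	Alberty
HCO3-	CHO3	-1	aqueous-solute	-586.77	-691.99	Alberty
CO3-2	CO3	-2	aqueous-solute	-527.81	-677.14	Alberty
H2O	H2O	0	liquid-water	-237.19	-285.83	Alberty
H+	H	1	proton	0.0	0.0	Alberty
acetate	C2H3O2	-1	aqueous-solute	-369.31	-486.01	Alberty
acetic-acid	C2H4O2	0	aqueous-solute	-396.45	-485.76	Alberty
ethanol	C2H6O	0	aqueous-solute	-181.64	-288.30	Alberty
propionate	C3H5O2	-1	aqueous-solute	-361.08	-513.35	AmendShock
butyrate	C4H7O2	-1	aqueous-solute	-352.63	-535.55	Alberty
butyric-acid	C4H8O2	0	aqueous-solute	-380.15		AmendShock
iso-butyrate	C4H7O2	-1	aqueous-solute	-346.46		AmendShock
1-butanol	C4H10O	0	aqueous-solute	-171.84	-327.18	AmendShock
caproate	C6H11O2	-1	aqueous-solute	-335.96		AmendShock
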