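name	formula	charge	phase	dGf0_kJ_mol	dHf0_kJ_mol	source
CO	C:1,O:1	0	aqueous	-120.00	-120.96	Amend & Shock 2001, aqueous 1 molal standard state
H2	H:2	0	aqueous	17.72	-4.04	Amend & Shock 2001, aqueous 1 molal standard state
CH4	C:1,H:4	0	aqueous	-34.35	-87.81	Amend & Shock 2001, aqueous 1 molal standard state
acetate	C:2,H:3,O:2	-1	aqueous	-369.31	-486.01	Shock & Helgeson 1990
HCO3	C:1,H:1,O:3	-1	aqueous	-586.85	-689.93	Shock et al. 1997
SO4	S:1,O:4	-2	aqueous	-744.53	-909.27	Shock et al. 1997
HS	H:1,S:1	-1	aqueous	12.05	-16.30	Shock et al. 1997
H2O	H:2,O:1	0	liquid-water	-237.18	-285.83	CODATA
H+	H:1	1	aqueous	0.0	0.0	convention
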