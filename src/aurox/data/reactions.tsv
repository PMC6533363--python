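id	equation	logK	n_electrons	drH	drS	E0	note
R1	Au(s) + O2- + 2 H2O(l) = Au(OH)4-	-1.91	0				superoxide oxidation of gold to Au(III) hydroxide; combination of R3, R4, 4xR5
R2	Au(s) + 0.75 O2(aq) + 2.5 H2O(l) = Au(OH)4- + H+	-16.09	0				dioxygen oxidation of gold to Au(III) hydroxide; combination of R6, R4, 4xR5
R3	Au(s) + O2- + 4 H+ = Au3+ + 2 H2O(l)	2.74	0	-122.82	-359.74		superoxide oxidation of gold at low pH; logK from drH, drS at 298 K
R4	Au3+ + 4 OH- = Au(OH)4-	51.35	0				Au(III) hydroxide complexation in alkaline solution
R5	H2O(l) = H+ + OH-	-14.00	0				water autoionization
R6	Au(s) + 0.75 O2(aq) + 3 H+ = Au3+ + 1.5 H2O(l)	-11.44	0				dioxygen oxidation of gold at low pH
R7	Au(s) = Au3+ + 3 e-	-77.11	3			-1.52	Au0/Au3+ half reaction; E0 applies to the oxidation as written (dG0 = -nFE0 convention)
R8	O2- + 4 H+ + 3 e- = 2 H2O(l)	79.84	3				superoxide/water reduction half reaction; logK derivable from R3 and R7
F:CO2(aq)	HCO3- + H+ = CO2(aq) + H2O(l)	6.38	0				carbonic acid pK1; from standard dGf values
F:CO3--	HCO3- = CO3-- + H+	-10.32	0				bicarbonate pK2; from standard dGf values
F:C(s)	HCO3- + 5 H+ + 4 e- = C(s) + 3 H2O(l)	21.86	0				graphite from bicarbonate; from standard dGf values
F:CH4(aq)	HCO3- + 9 H+ + 8 e- = CH4(aq) + 3 H2O(l)	27.89	0				methane from bicarbonate; from standard dGf values
F:SO4--	0.5 S2O3-- + 2.5 H2O(l) = SO4-- + 5 H+ + 4 e-	-19.31	0				sulfate from thiosulfate; from standard dGf values
F:HSO4-	0.5 S2O3-- + 2.5 H2O(l) = HSO4- + 4 H+ + 4 e-	-17.33	0				bisulfate from thiosulfate; from standard dGf values
F:S(s)	0.5 S2O3-- + 3 H+ + 2 e- = S(s) + 1.5 H2O(l)	16.57	0				elemental sulfur from thiosulfate; from standard dGf values
F:H2S(aq)	0.5 S2O3-- + 5 H+ + 4 e- = H2S(aq) + 1.5 H2O(l)	21.45	0				hydrogen sulfide from thiosulfate; from standard dGf values
F:HS-	0.5 S2O3-- + 4 H+ + 4 e- = HS- + 1.5 H2O(l)	14.45	0				bisulfide from thiosulfate; from standard dGf values
F:Au+	Au(s) = Au+ + e-	-28.58	0				aurous ion from metal; E0(Au+/Au) = 1.69 V
F:Au3+	Au(s) = Au3+ + 3 e-	-77.11	0				auric ion from metal; consistent with E0 = 1.52 V reduction
F:AuOH(aq)	Au(s) + H2O(l) = AuOH(aq) + H+ + e-	-31.38	0				Au(I) hydrolysis, first step; estimate (editable)
F:Au(OH)2-	Au(s) + 2 H2O(l) = Au(OH)2- + 2 H+ + e-	-38.38	0				Au(I) hydrolysis, second step; estimate (editable)
F:Au(OH)4-	Au(s) + 4 H2O(l) = Au(OH)4- + 4 H+ + 3 e-	-81.76	0				Au(III) tetrahydroxide from metal; from R7 with R4 and water autoionization
F:AuHS(aq)	Au(s) + HS- = AuHS(aq) + e-	-4.08	0				Au(I) monobisulfide from metal; solubility-study estimate (editable)
F:Au(HS)2-	Au(s) + 2 HS- = Au(HS)2- + e-	1.42	0				Au(I) bis-bisulfide from metal; solubility-study estimate (editable)
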