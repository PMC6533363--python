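name	formula	charge	phase	dHf	S0	note
e-		-1	aqueous			electron pseudo-species
H+	H	1	aqueous			proton; unit-activity convention via pH
OH-	OH	-1	aqueous			hydroxide
H2O(l)	H2O	0	liquid			water, unit activity
O2(aq)	O2	0	aqueous			dissolved molecular oxygen
O2-	O2	-1	gas			superoxide radical anion
Au(s)	Au	0	solid			metallic gold, unit activity
Au+	Au	1	aqueous			aurous ion
Au3+	Au	3	aqueous			auric ion
AuOH(aq)	AuOH	0	aqueous			Au(I) hydroxide complex
Au(OH)2-	Au(OH)2	-1	aqueous			Au(I) dihydroxide complex
Au(OH)4-	Au(OH)4	-1	aqueous			Au(III) tetrahydroxide complex
AuHS(aq)	AuHS	0	aqueous			Au(I) bisulfide complex
Au(HS)2-	Au(HS)2	-1	aqueous			Au(I) bis-bisulfide complex
CH4(aq)	CH4	0	aqueous			dissolved methane
C(s)	C	0	solid			elemental carbon (graphite)
CO2(aq)	CO2	0	aqueous			dissolved carbon dioxide
HCO3-	HCO3	-1	aqueous			bicarbonate; carbon-system anchor
CO3--	CO3	-2	aqueous			carbonate
H2S(aq)	H2S	0	aqueous			dissolved hydrogen sulfide
HS-	HS	-1	aqueous			bisulfide
S(s)	S	0	solid			elemental sulfur (rhombic)
HSO4-	HSO4	-1	aqueous			bisulfate
SO4--	SO4	-2	aqueous			sulfate
S2O3--	S2O3	-2	aqueous			thiosulfate; sulfur-system anchor
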