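name	formula_gained	formula_lost
methylation (+CH2)	CH2
hydrogenation (+H2)	H2
hydration (+H2O)	H2O
amination (+NH3)	NH3
oxidation (+O)	O
formylation (+CO)	CO
ketene addition (+C2H2O)	C2H2O
carboxylation (+CO2)	CO2
phosphate addition (+HPO3)	HPO3
sulfation (+SO3)	SO3
ethenylation (+C2H2)	C2H2
propylation (+C3H6)	C3H6
glycine conjugation	C2H5NO2	H2O
alanine conjugation	C3H7NO2	H2O
serine conjugation	C3H7NO3	H2O
glutamate conjugation	C5H9NO4	H2O
taurine conjugation	C2H7NO3S	H2O
glutathione conjugation	C10H17N3O6S	H2O
pentose condensation	C5H10O5	H2O
hexose condensation	C6H12O6	H2O
glucuronate condensation	C6H10O7	H2O
phosphorylation	H3PO4	H2O
sulfate condensation	H2SO4	H2O
glycerol condensation	C3H8O3	H2O
choline condensation	C5H13NO	H2O
ethanolamine condensation	C2H7NO	H2O
lauric acid condensation (C12:0)	C12H24O2	H2O
myristic acid condensation (C14:0)	C14H28O2	H2O
myristoleic acid condensation (C14:1)	C14H26O2	H2O
palmitic acid condensation (C16:0)	C16H32O2	H2O
palmitoleic acid condensation (C16:1)	C16H30O2	H2O
stearic acid condensation (C18:0)	C18H36O2	H2O
oleic acid condensation (C18:1)	C18H34O2	H2O
linoleic acid condensation (C18:2)	C18H32O2	H2O
linolenic acid condensation (C18:3)	C18H30O2	H2O
arachidic acid condensation (C20:0)	C20H40O2	H2O
mead acid condensation (C20:3)	C20H34O2	H2O
arachidonic acid condensation (C20:4)	C20H32O2	H2O
EPA condensation (C20:5)	C20H30O2	H2O
behenic acid condensation (C22:0)	C22H44O2	H2O
DPA condensation (C22:5)	C22H34O2	H2O
DHA condensation (C22:6)	C22H32O2	H2O
lignoceric acid condensation (C24:0)	C24H48O2	H2O
nervonic acid condensation (C24:1)	C24H46O2	H2O
androstane backbone condensation	C19H32	H2
DHEA condensation	C19H28O2	H2O
pregnenolone condensation	C21H32O2	H2O
cortisol condensation	C21H30O5	H2O
cholesterol condensation	C27H46O	H2O
cholesterol addition	C27H46O
pregnenolone addition	C21H32O2
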