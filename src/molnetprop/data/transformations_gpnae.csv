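name,formula
Desaturation,H2
Methylene,CH2
Hydroxylation,O
Water,H2O
Ethylene,C2H4
Acetylene,C2H2
Formaldehyde,CH2O
Carbon monoxide,CO
Carbon dioxide,CO2
Acetyl,C2H2O
Acetaldehyde,C2H4O
Propenoyl,C3H4O
Malonyl,C3H2O3
Glycerol,C3H8O3
Glyceryl,C3H6O2
Phosphate,HPO3
Sulfate,SO3
Hexose,C6H10O5
Deoxyhexose,C6H10O4
Pentose,C5H8O4
Glucuronic acid,C6H8O6
Ethanolamine,C2H5N
Phosphoethanolamine,C2H6NO3P
Glycerophosphate,C3H7O5P
Imine,NH
Propylene,C3H6
Butylene,C4H8
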