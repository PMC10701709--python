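name,formula
Desaturation,H2
Methylene,CH2
Ethylene,C2H4
Acetylene,C2H2
Phosphate,HPO3
Angelicyl,C5H6O
Hexose,C6H10O5
Ascaroside unit,C13H22O5
Indole carboxyl,C9H5NO
Propanone,C3H6O
Acetaldehyde,C2H4O
Hydroxylation,O
Water,H2O
Carbon dioxide,CO2
Acetyl,C2H2O
Glucuronic acid,C6H8O6
Anthranilate,C7H5NO
Tyramine,C8H9NO
Benzoyl,C7H4O
Pentose,C5H8O4
Glycerol,C3H8O3
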