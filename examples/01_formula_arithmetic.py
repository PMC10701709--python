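"""Molecular formula arithmetic, monoisotopic masses and anion m/z."""

from molnetprop import ion_mz, monoisotopic_mass, parse_formula

hexose = parse_formula("C6H10O5")
print(f"hexose {hexose}: {monoisotopic_mass(hexose):.4f} u")
print(f"phosphate HPO3:  {monoisotopic_mass(parse_formula('HPO3')):.4f} u")

# electron-inclusive anion m/z of deprotonated glycerol 3-phosphate
g3p_anion = parse_formula("C3H8O6P")
print(f"[C3H8O6P]- m/z:  {ion_mz(g3p_anion, -1):.4f}")

# formula arithmetic: a GPNAE plus a hexose gives its glyco-variant
gpnae = parse_formula("C18H38NO7P")
print(f"GPNAE 13:0 + hexose = {gpnae + hexose}")

# The masses are the values a high-resolution instrument should read for
# these species in negative mode; 162.0528 u is the neutral hexose gain
# that links a metabolite to its glycoside.
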