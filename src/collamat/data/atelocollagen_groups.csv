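# Ionizable-group inventory of one atelocollagen (bovine collagen type I) molecule.
# pKa at 25 C and zero ionic strength; ionization enthalpy in kJ/mol.
# Asp and His reference pKa values are calibrated against the charge anchors
# (see docs/methods.md); pair_sign is -1 for -COOH/-COO- and +1 for -NH3+/-NH2.
name,count,pka_ref,pair_sign,ionization_enthalpy
Asp,90,4.10,-1,1.0
Glu,150,4.25,-1,1.0
Pro-Cterm,3,3.60,-1,1.0
His,14,6.23,1,29.5
Arg,162,12.10,1,51.9
Lys,89,10.67,1,53.0
Gly-Nterm,3,9.00,1,45.0
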