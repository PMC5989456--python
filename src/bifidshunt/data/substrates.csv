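name,hexose_equivalents,glcnac_residues,carbon_atoms,molar_mass
glucose,1,0,6,180.16
galactose,1,0,6,180.16
lactose,2,0,12,342.30
glcnac,1,1,8,221.21
lnt,4,1,26,707.63
lnnt,4,1,26,707.63
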