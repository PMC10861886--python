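res_name,atom_name,charge
# Formal-charge template at physiological pH: charge is distributed evenly over
# the equivalent terminal atoms of each charged side-chain group.  All atoms not
# listed carry charge 0.  Histidine is treated as neutral.  Override by passing
# a custom table to holoprot.structure.annotate(charge_table=...).
ASP,OD1,-0.5
ASP,OD2,-0.5
GLU,OE1,-0.5
GLU,OE2,-0.5
LYS,NZ,1.0
ARG,NH1,0.5
ARG,NH2,0.5
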