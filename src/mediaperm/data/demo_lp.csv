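# Synthetic demo hydraulic conductances (m s^-1 Pa^-1), one per specimen.
# Lp is an experimental input the simulations cannot produce; these values
# are chosen to be internally consistent with the synthetic-permeability
# scale of the demo pipeline (so the medial fraction of wall resistance
# and its decrease under constriction are qualitatively reproduced).
specimen_id,condition,lp
b1,baseline,9.2e-12
b2,baseline,8.8e-12
b3,baseline,9.0e-12
b4,baseline,9.1e-12
b5,baseline,8.9e-12
c1,constricted,6.1e-12
c2,constricted,5.9e-12
c3,constricted,6.0e-12
c4,constricted,5.95e-12
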