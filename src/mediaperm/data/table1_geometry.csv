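quantity,condition,mean,sem,n
phi_ecm,baseline,0.60,0.01,5
phi_ecm,constricted,0.68,0.01,4
thickness_um,baseline,27.7,2.2,5
thickness_um,constricted,33.2,1.7,4
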