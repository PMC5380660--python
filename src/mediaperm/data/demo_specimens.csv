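# Synthetic demo specimen table for the resistance decomposition CLI.
# k11 values are the documented per-block radial permeabilities on the
# 1e-18 m^2 scale; thickness values scatter around the documented group
# means (27.7 / 33.2 um); lp values are plausible synthetic conductances.
specimen_id,condition,lp,thickness_um,k11
b1,baseline,1.42e-10,28.1,4.49e-18
b2,baseline,1.31e-10,27.2,4.50e-18
b3,baseline,1.40e-10,29.5,4.37e-18
b4,baseline,1.33e-10,25.9,4.11e-18
b5,baseline,1.38e-10,27.8,4.17e-18
c1,constricted,9.4e-11,33.5,7.20e-18
c2,constricted,8.8e-11,32.6,6.95e-18
c3,constricted,9.3e-11,34.0,6.95e-18
c4,constricted,8.9e-11,32.7,6.79e-18
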