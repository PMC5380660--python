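condition,block,k11_1e18_m2
baseline,1,4.49
baseline,2,4.50
baseline,3,4.37
baseline,4,4.11
baseline,5,4.17
constricted,1,7.20
constricted,2,6.95
constricted,3,6.95
constricted,4,6.79
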