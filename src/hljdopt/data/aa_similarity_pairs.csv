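metabolite_a,metabolite_b,similarity
Leu,Ile,0.9
Leu,Val,0.8
Ile,Val,0.8
Phe,Tyr,0.85
Phe,Trp,0.7
Tyr,Trp,0.7
Asp,Glu,0.85
Gln,Glu,0.85
Asp,Gln,0.7
Ser,Gly,0.8
Ser,Thr,0.8
Gly,Ala,0.75
Ala,2-ABA,0.8
Arg,Orn,0.8
Lys,Orn,0.75
Met,Cys,0.7
Tau,Cys,0.7
GABA,Glu,0.75
Pro,Glu,0.6
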