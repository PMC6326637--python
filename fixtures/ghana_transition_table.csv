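from_category,to_category,probability,standard_error
CHPS,HCA,0.01,0.001
HCA,HCB,0.033,0.002
HCB,PolyC,0.028,0.002
PolyC,PHA,0.042,0.002
PHA,PHB,0.167,0.005
PHB,PHC,0.129,0.004
PHC,PHD,0.084,0.003
PHD,RH,0.021,0.002
RH,EmTH,0.091,0.003
EmTH,EsTH,0.001,0.0
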