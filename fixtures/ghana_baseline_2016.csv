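region,category,count
Ghana,CHPS,4449.0
Ghana,HCA,903.0
Ghana,HCB,158.0
Ghana,PolyC,40.0
Ghana,PHA,96.0
Ghana,PHB,49.0
Ghana,PHC,29.0
Ghana,PHD,14.0
Ghana,RH,7.0
Ghana,EmTH,2.0
Ghana,EsTH,2.0
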