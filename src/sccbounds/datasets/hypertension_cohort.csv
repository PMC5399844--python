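x1,x2,cases,total
low,young,79,1810
low,old,100,681
high,young,153,1385
high,old,278,1021
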