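x1,x2,cases,controls
Val/Val,Arg/Arg,157,186
Val/Val,Arg/Gln,124,142
Val/Val,Gln/Gln,26,31
Val/Ala,Arg/Arg,273,286
Val/Ala,Arg/Gln,180,183
Val/Ala,Gln/Gln,56,53
Ala/Ala,Arg/Arg,105,77
Ala/Ala,Arg/Gln,59,55
Ala/Ala,Gln/Gln,20,5
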