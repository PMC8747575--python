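name,coefficient
AE,-23.723
QM,0.234
nAromBond,-3.303
SsOH,3.601
SssO,-0.33
SsCH3,0.477
SsNH2,2.753
SHBa,-0.65
SHdsCH,1.301
nAcid,-5.580
SssCH2,-0.618
SHBd,-15.805
nHeavyAtom,15.53
intercept,10.667
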