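name
AE
QM
nAromBond
nHeavyAtom
nAcid
SsOH
SssO
SsCH3
SsNH2
SHBa
SHdsCH
SssCH2
SHBd
eta
chi
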