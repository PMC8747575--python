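name,dhvap_kjmol,role
methane,8.19,range_min
heptanoic acid,69.00,range_max
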