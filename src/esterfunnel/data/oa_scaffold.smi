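CC1(CCC2(CCC3(C(=CCC4C3(CCC5C4(CCC(C5(C)C)[OH:1])C)C)C2C1)C)C(=O)O)C	oleanolic_acid
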