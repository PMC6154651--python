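# Functional-class atom typing for the feature-class circular fingerprint.
# Each atom's initial invariant is the 6-bit mask of these classes, in file
# order (bit 0 = first row). Columns: name <TAB> smarts
name	smarts
hbond_acceptor	[$([#8]),$([#7;!$([NX3][CX3]=[OX1]);!$([nX3H1])])]
hbond_donor	[#7,#8;!H0]
positively_ionizable	[$([#7+]),$([NX3;H1,H2;!$([NX3][CX3]=[OX1]);!$([NX3]a)])]
negatively_ionizable	[$([#8-]),$([OX2H1][CX3]=[OX1]),$([OX2H1][SX4](=[OX1])=[OX1]),$([OX2H1][PX4]=[OX1])]
aromatic	[a]
halogen	[F,Cl,Br,I]
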