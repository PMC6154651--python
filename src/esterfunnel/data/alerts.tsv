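# Structural-alert catalogue: reactive/unstable groups and non-druglike
# chemotypes excluded during carboxylic-acid library curation.
# Columns: name <TAB> category <TAB> pattern
# pattern is SMARTS, or "element:X,Y,Z" for a plain element scan.
# Notes:
#  - long_chain_fatty_acid: an unbranched sp3 chain of >=8 carbons terminating
#    in the COOH (first seven strictly CH2, eighth CH2 or CH3).
#  - ion-exchange-resin-like records are covered by quaternary_ammonium; no
#    polymer/repeat-unit records exist in the small-molecule inputs.
name	category	pattern
aminonitrile	reactive	[NX3;!$([NX3][CX3]=[OX1])][CX4][CX2]#[NX1]
thionitrile	reactive	[#16][CX2]#[NX1]
epoxide	reactive	[OX2r3]1[#6r3][#6r3]1
aziridine	reactive	[NX3r3]1[#6r3][#6r3]1
disulfide	reactive	[#16X2][#16X2]
nitrogen_oxide	reactive	[$([#7+][#8X1-]),$([#7]=[OX1])]
azo	reactive	[#6][NX2]=[NX2][#6]
beta_lactam	reactive	[CX3r4](=[OX1])[NX3r4]
long_chain_fatty_acid	non_druglike	[OX2H1][CX3](=[OX1])[CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4;H2,H3]
gem_dicarboxylic	non_druglike	[CX4]([CX3](=[OX1])[OX2H1])[CX3](=[OX1])[OX2H1]
quaternary_ammonium	non_druglike	[NX4+;!$([NX4+][#8-])]
boron_silicon_selenium	non_druglike	element:B,Si,Se
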