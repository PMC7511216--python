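# B. methanolicus MGA3 central carbon metabolism, mannitol condition.
# Mannitol enters via PTS as mannitol 1-phosphate and is oxidized to Fru6P
# (lumped into manupt).  Glycolytic intermediates are lumped as displayed in
# the stationary flux maps: no Hex6P/DHAP/PGA/Aco pools, aldolase splits
# FruBP directly into two trioses, pgk lumps the lower glycolysis to PEP.
# Acetate overflow is exported from acetyl-CoA (out_Ac).  Free mannitol is
# rotationally symmetric, so PTS phosphorylation scrambles C1/C6.
MET Mntl 6 source
MET Fru6P 6 internal
MET Glc6P 6 internal
MET Gnt6P 6 internal
MET Ribu5P 5 internal
MET Xyl5P 5 internal
MET Rib5P 5 internal
MET Sed7P 7 internal
MET E4P 4 internal
MET FruBP 6 internal
MET GA3P 3 internal
MET PEP 3 internal
MET Pyr 3 internal
MET AcCoA 2 internal
MET Cit 6 internal
MET ICit 6 internal
MET AKG 5 internal
MET Suc 4 internal
MET Fum 4 internal
MET Mal 4 internal
MET OAA 4 internal
MET CO2 1 internal
SYM Mntl
SYM Suc
SYM Fum
RXN manupt irr 1 Mntl[abcdef] -> 1 Fru6P[abcdef]
RXN pgi rev 1 Fru6P[abcdef] -> 1 Glc6P[abcdef]
RXN zwf irr 1 Glc6P[abcdef] -> 1 Gnt6P[abcdef]
RXN gnd irr 1 Gnt6P[abcdef] -> 1 Ribu5P[bcdef] + 1 CO2[a]
RXN rpe rev 1 Ribu5P[abcde] -> 1 Xyl5P[abcde]
RXN rpi rev 1 Ribu5P[abcde] -> 1 Rib5P[abcde]
RXN tkt1 rev 1 Xyl5P[abcde] + 1 Rib5P[fghij] -> 1 Sed7P[abfghij] + 1 GA3P[cde]
RXN ta rev 1 Sed7P[abcdefg] + 1 GA3P[hij] -> 1 Fru6P[abchij] + 1 E4P[defg]
RXN tkt2 rev 1 Xyl5P[abcde] + 1 E4P[fghi] -> 1 Fru6P[abfghi] + 1 GA3P[cde]
RXN pfk irr 1 Fru6P[abcdef] -> 1 FruBP[abcdef]
RXN fba rev 1 FruBP[abcdef] -> 1 GA3P[cba] + 1 GA3P[def]
RXN pgk rev 1 GA3P[abc] -> 1 PEP[abc]
RXN pyk irr 1 PEP[abc] -> 1 Pyr[abc]
RXN pdh irr 1 Pyr[abc] -> 1 AcCoA[bc] + 1 CO2[a]
RXN cs irr 1 OAA[abcd] + 1 AcCoA[ef] -> 1 Cit[dcbfea]
RXN acn rev 1 Cit[abcdef] -> 1 ICit[abcdef]
RXN idh irr 1 ICit[abcdef] -> 1 AKG[abcde] + 1 CO2[f]
RXN akgdh irr 1 AKG[abcde] -> 1 Suc[bcde] + 1 CO2[a]
RXN sdh rev 1 Suc[abcd] -> 1 Fum[abcd]
RXN fuma rev 1 Fum[abcd] -> 1 Mal[abcd]
RXN maldh rev 1 Mal[abcd] -> 1 OAA[abcd]
RXN pyc irr 1 Pyr[abc] + 1 CO2[d] -> 1 OAA[abcd]
RXN mae irr 1 Mal[abcd] -> 1 Pyr[abc] + 1 CO2[d]
RXN out_Ac irr 1 AcCoA[ab] -> out
RXN co2out irr 1 CO2[a] -> out
RXN bm_glc6p irr 1 Glc6P[abcdef] -> out
RXN bm_fru6p irr 1 Fru6P[abcdef] -> out
RXN bm_rib5p irr 1 Rib5P[abcde] -> out
RXN bm_e4p irr 1 E4P[abcd] -> out
RXN bm_ga3p irr 1 GA3P[abc] -> out
RXN bm_pep irr 1 PEP[abc] -> out
RXN bm_pyr irr 1 Pyr[abc] -> out
RXN bm_accoa irr 1 AcCoA[ab] -> out
RXN bm_oaa irr 1 OAA[abcd] -> out
RXN bm_akg irr 1 AKG[abcde] -> out
BIO Glc6P 0.205
BIO Fru6P 0.071
BIO Rib5P 0.898
BIO E4P 0.361
BIO GA3P 1.625
BIO PEP 0.519
BIO Pyr 2.833
BIO AcCoA 3.748
BIO OAA 1.787
BIO AKG 1.079
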