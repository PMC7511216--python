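# B. methanolicus MGA3 central carbon metabolism, methanol condition.
# RuMP assimilation (hps/phi), cyclic dissimilation via zwf/gnd, linear
# formaldehyde detoxification (detox, lumped methylene-THF/formate branch),
# SBPase and TA variants of the regeneration part, full TCA cycle with
# explicit CO2 pool, anaplerosis via pyc and mae (no PEP carboxykinase).
# Glycolytic intermediates are kept explicit; pool sizes (umol/gDCW) are
# order-of-magnitude defaults chosen so the labeling transient after a
# tracer pulse spans a few minutes of sampling.
MET MeOH 1 source
MET For 1 internal 2.5
MET Hex6P 6 internal 10
MET Fru6P 6 internal 75
MET Glc6P 6 internal 100
MET Gnt6P 6 internal 25
MET Ribu5P 5 internal 15
MET Xyl5P 5 internal 20
MET Rib5P 5 internal 15
MET Sed7P 7 internal 50
MET SBP 7 internal 5
MET E4P 4 internal 5
MET FruBP 6 internal 100
MET DHAP 3 internal 25
MET GA3P 3 internal 15
MET PGA 3 internal 75
MET PEP 3 internal 50
MET Pyr 3 internal 25
MET AcCoA 2 internal 5
MET Cit 6 internal 50
MET Aco 6 internal 5
MET ICit 6 internal 10
MET AKG 5 internal 25
MET Suc 4 internal 25
MET Fum 4 internal 15
MET Mal 4 internal 40
MET OAA 4 internal 5
MET CO2 1 internal 50
SYM Suc
SYM Fum
RXN mdh irr 1 MeOH[a] -> 1 For[a]
RXN hps irr 1 For[a] + 1 Ribu5P[bcdef] -> 1 Hex6P[abcdef]
RXN phi irr 1 Hex6P[abcdef] -> 1 Fru6P[abcdef]
RXN detox irr 1 For[a] -> 1 CO2[a]
RXN pgi rev 1 Fru6P[abcdef] -> 1 Glc6P[abcdef]
RXN zwf irr 1 Glc6P[abcdef] -> 1 Gnt6P[abcdef]
RXN gnd irr 1 Gnt6P[abcdef] -> 1 Ribu5P[bcdef] + 1 CO2[a]
RXN rpe rev 1 Ribu5P[abcde] -> 1 Xyl5P[abcde]
RXN rpi rev 1 Ribu5P[abcde] -> 1 Rib5P[abcde]
RXN tkt1 rev 1 Xyl5P[abcde] + 1 Rib5P[fghij] -> 1 Sed7P[abfghij] + 1 GA3P[cde]
RXN ta rev 1 Sed7P[abcdefg] + 1 GA3P[hij] -> 1 Fru6P[abchij] + 1 E4P[defg]
RXN tkt2 rev 1 Xyl5P[abcde] + 1 E4P[fghi] -> 1 Fru6P[abfghi] + 1 GA3P[cde]
RXN sba rev 1 DHAP[abc] + 1 E4P[defg] -> 1 SBP[cbadefg]
RXN glpx irr 1 SBP[abcdefg] -> 1 Sed7P[abcdefg]
RXN pfk irr 1 Fru6P[abcdef] -> 1 FruBP[abcdef]
RXN fba rev 1 FruBP[abcdef] -> 1 DHAP[cba] + 1 GA3P[def]
RXN tpi rev 1 DHAP[abc] -> 1 GA3P[cba]
RXN pgk rev 1 GA3P[abc] -> 1 PGA[abc]
RXN eno rev 1 PGA[abc] -> 1 PEP[abc]
RXN pyk irr 1 PEP[abc] -> 1 Pyr[abc]
RXN pdh irr 1 Pyr[abc] -> 1 AcCoA[bc] + 1 CO2[a]
RXN cs irr 1 OAA[abcd] + 1 AcCoA[ef] -> 1 Cit[dcbfea]
RXN acn1 rev 1 Cit[abcdef] -> 1 Aco[abcdef]
RXN acn2 rev 1 Aco[abcdef] -> 1 ICit[abcdef]
RXN idh irr 1 ICit[abcdef] -> 1 AKG[abcde] + 1 CO2[f]
RXN akgdh irr 1 AKG[abcde] -> 1 Suc[bcde] + 1 CO2[a]
RXN sdh rev 1 Suc[abcd] -> 1 Fum[abcd]
RXN fuma rev 1 Fum[abcd] -> 1 Mal[abcd]
RXN maldh rev 1 Mal[abcd] -> 1 OAA[abcd]
RXN pyc irr 1 Pyr[abc] + 1 CO2[d] -> 1 OAA[abcd]
RXN mae irr 1 Mal[abcd] -> 1 Pyr[abc] + 1 CO2[d]
RXN co2out irr 1 CO2[a] -> out
RXN bm_glc6p irr 1 Glc6P[abcdef] -> out
RXN bm_fru6p irr 1 Fru6P[abcdef] -> out
RXN bm_rib5p irr 1 Rib5P[abcde] -> out
RXN bm_e4p irr 1 E4P[abcd] -> out
RXN bm_ga3p irr 1 GA3P[abc] -> out
RXN bm_pga irr 1 PGA[abc] -> out
RXN bm_pep irr 1 PEP[abc] -> out
RXN bm_pyr irr 1 Pyr[abc] -> out
RXN bm_accoa irr 1 AcCoA[ab] -> out
RXN bm_oaa irr 1 OAA[abcd] -> out
RXN bm_akg irr 1 AKG[abcde] -> out
BIO Glc6P 0.205
BIO Fru6P 0.071
BIO Rib5P 0.898
BIO E4P 0.361
BIO GA3P 0.129
BIO PGA 1.496
BIO PEP 0.519
BIO Pyr 2.833
BIO AcCoA 3.748
BIO OAA 1.787
BIO AKG 1.079
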