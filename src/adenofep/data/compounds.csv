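compound_id,alt_label,series,r2,r4,r6,smiles,a1,a2a,a2b,a3
18a,,I,NH2,Ph,Ph,,4.42 ± 0.16,18.6 ± 3.4,33%,1%
18b,,I,NH2,2-F-Ph,Ph,,6.44 ± 1.25,17.6 ± 2.8,34%,8%
18c,,I,NH2,2-Cl-Ph,Ph,,5%,1%,9%,1%
18d,,I,NH2,2-MeO-Ph,Ph,,13.1 ± 3.2,17.7 ± 2.1,14%,8%
18e,,I,NH2,3-F-Ph,Ph,,13.4 ± 4.1,19.5 ± 3.3,186 ± 11,2%
18f,,I,NH2,3-Cl-Ph,Ph,,4.25 ± 1.10,15.5 ± 2.4,177 ± 13,1%
18g,,I,NH2,3-MeO-Ph,Ph,,2.08 ± 0.16,6.91 ± 1.52,31.2 ± 6.3,12%
18h,,I,NH2,3-OH-Ph,Ph,,1.49 ± 0.43,10.2 ± 3.52,50.1 ± 8.2,9%
18i,,I,NH2,3-CN-Ph,Ph,,6.49 ± 1.14,84.1 ± 11.7,19%,1%
18j,,I,NH2,4-F-Ph,Ph,,4.19 ± 1.16,16.3 ± 2.9,7%,10%
18k,,I,NH2,4-Br-Ph,Ph,,9.19 ± 2.81,21.9 ± 5.0,8%,2%
18l,,I,NH2,4-MeO-Ph,Ph,,7.16 ± 2.03,46.0 ± 3.2,8%,11%
18m,,I,NH2,4-OH-Ph,Ph,,4.14 ± 0.55,26.5 ± 1.6,14%,18%
18n,,I,NH2,4-Me-Ph,Ph,,5.38 ± 1.36,8.93 ± 0.12,28%,16%
18o,,I,NH2,"2,4-F-Ph",Ph,,4.00 ± 1.82,15.5 ± 2.21,7%,12%
18p,,I,NH2,"2,4-Cl-Ph",Ph,,35%,29%,2%,7%
18q,,I,NH2,"2,4-MeO-Ph",Ph,,3.98 ± 0.74,10.2 ± 1.83,13%,1%
18r,,I,NH2,"3,5-F-Ph",Ph,,27%,24%,1%,1%
18s,,I,NH2,"3,5-Cl-Ph",Ph,,15.9 ± 2.11,95.4 ± 16.5,1%,10%
18t,,I,NH2,"3,5-MeO-Ph",Ph,,2.58 ± 0.67,1.73 ± 0.33,45.1 ± 3.7,3%
18u,,I,NH2,"3,4-OCH2O-Ph",Ph,,1.75 ± 0.31,10.2 ± 1.09,43.3 ± 4.2,12%
18v,,I,NH2,"3,4,5-MeO-Ph",Ph,,2.58 ± 0.05,0.95 ± 0.07,3%,13%
18w,,I,NH2,"2,4,6-F-Ph",Ph,,2%,2%,2%,19%
18x,,I,NH2,2-furyl,Ph,,9.70 ± 1.20,10.1 ± 3.7,21.8 ± 2.7,9%
18y,,I,NH2,2-thienyl,Ph,,17.3 ± 4.4,24.9 ± 4.6,40.6 ± 3.7,41%
18z,,I,NH2,3-furyl,Ph,,18.7 ± 3.4,52.1 ± 5.1,37%,3%
18aa,,I,NH2,3-thienyl,Ph,,5.25 ± 2.16,20.6 ± 2.7,40%,1%
18ab,,I,NH2,4-pyridyl,Ph,,216 ± 23,676 ± 27,1%,12%
18ac,,I,NH2,3-pyridyl,Ph,,19.6 ± 1.47,36.4 ± 5.7,20%,1%
18ad,,I,NH2,cPent,Ph,,10%,12%,1%,19%
18ae,,I,NH2,cHex,Ph,,20%,10%,5%,2%
18af,,I,NH2,2-naphthyl,Ph,,8.27 ± 2.10,5.78 ± 1.16,3%,8%
18ag,,I,NH2,4-Ph-Ph,Ph,,6500 ± 451,16%,1%,1%
18ah,,I,NH2,3-Cl-Ph,3-Cl-Ph,,4.82 ± 0.37,35.3 ± 7.7,73.6 ± 6.8,1%
18ai,,I,NH2,3-Cl-Ph,"3,5-Cl-Ph",,7.81 ± 1.43,190 ± 22,9%,2%
18aj,,I,NH2,3-Cl-Ph,"3,4-OCH2O-Ph",,5.61 ± 0.74,101 ± 15,386 ± 15,26%
18ak,,I,NH2,4-F-Ph,"3,4-OCH2O-Ph",,12.5 ± 2.3,61.0 ± 4.9,2%,22%
18al,,I,NH2,4-MeO-Ph,4-MeO-Ph,,74.3 ± 3.4,2%,1%,9%
18am,,I,NH2,2-furyl,4-F-Ph,,9.08 ± 1.16,5.72 ± 0.26,13.9 ± 3.7,11%
19a,,II,NHMe,Ph,Ph,,9.14 ± 2.21,711 ± 43,14%,2%
19b,,II,NHEt,Ph,Ph,,5.82 ± 1.16,357 ± 21,17%,16%
19c,,II,NHPh,Ph,Ph,,45.6 ± 6.7,55.1 ± 4.3,34%,4%
19d,,II,NHMe,2-F-Ph,Ph,,29.5 ± 2.3,15%,47.8 ± 3.8,3%
19e,,II,NHPh,2-F-Ph,Ph,,6.25 ± 1.02,52.5 ± 6.2,107 ± 10,2%
19f,,II,NHMe,2-Cl-Ph,Ph,,2%,2%,6%,2%
19g,,II,NHPh,2-Cl-Ph,Ph,,16%,5%,14%,1%
19h,,II,NHMe,2-MeO-Ph,Ph,,17%,1%,9%,1%
19i,,II,NHPh,2-MeO-Ph,Ph,,2%,2%,5%,9%
19j,,II,NHMe,3-F-Ph,Ph,,28.5 ± 2.7,11%,358 ± 27,1%
19k,,II,NHPh,3-F-Ph,Ph,,1%,12%,9%,9%
19l,ISAM-CV207,II,NHMe,3-Cl-Ph,Ph,,15.7 ± 3.6,2%,12%,2%
19m,,II,NHEt,3-Cl-Ph,Ph,,5.10 ± 1.8,295 ± 27,33%,2%
19n,ISAM-CV245,II,NHPh,3-Cl-Ph,Ph,,22%,46.3 ± 2.5,12%,15%
19o,,II,NHMe,3-OH-Ph,Ph,,2.48 ± 0.71,105 ± 8,29%,9%
19p,,II,NHPh,3-OH-Ph,Ph,,18.3 ± 1.6,71.2 ± 5.3,40%,13%
19q,,II,NHMe,3-MeO-Ph,Ph,,13.2 ± 4.1,82.6 ± 4.9,31%,3%
19r,,II,NHPh,3-MeO-Ph,Ph,,95.5 ± 11.7,133 ± 11,15%,9%
19s,,II,NHMe,3-CN-Ph,Ph,,2.99 ± 0.71,78.5 ± 6.7,34.6 ± 5.7,1%
19t,,II,NHEt,3-CN-Ph,Ph,,2.46 ± 0.18,155 ± 21,14.2 ± 3.8,1%
19u,,II,NHPh,3-CN-Ph,Ph,,18.2 ± 3.1,19%,16.4 ± 2.2,2%
19v,ISAM-CV209,II,NHMe,4-F-Ph,Ph,,23.2 ± 1.2,9%,13%,1%
19w,,II,NHPh,4-F-Ph,Ph,,36.3 ± 4.1,10%,51.7 ± 3.1,9%
19x,,II,NHMe,4-Br-Ph,Ph,,12%,3%,8%,2%
19y,,II,NHPh,4-Br-Ph,Ph,,5%,8%,1%,43%
19z,,II,NHMe,4-OH-Ph,Ph,,44.6 ± 3.2,7%,2%,8%
19aa,,II,NHPh,4-OH-Ph,Ph,,4%,9%,1%,1%
19ab,,II,NHMe,4-MeO-Ph,Ph,,57.5 ± 2.7,6%,1%,1%
19ac,,II,NHPh,4-MeO-Ph,Ph,,24%,51.4 ± 3.7,186 ± 15,31%
19ad,,II,NHMe,4-Me-Ph,Ph,,28.0 ± 9.3,11%,474 ± 32,7%
19ae,,II,NHPh,4-Me-Ph,Ph,,37.9 ± 5.7,157 ± 16,4%,1%
19af,ISAM-CV216,II,NHMe,"2,4-F-Ph",Ph,,22.6 ± 7.0,3%,3%,2%
19ag,,II,NHPh,"2,4-F-Ph",Ph,,1%,2%,2%,29%
19ah,,II,NHMe,"3,5-F-Ph",Ph,,16%,1%,15%,2%
19ai,,II,NHPh,"3,5-F-Ph",Ph,,1%,1%,2%,1%
19aj,ISAM-CV218,II,NHMe,"3,5-Cl-Ph",Ph,,27.0 ± 3.6,2%,1%,2%
19ak,,II,NHEt,"3,5-Cl-Ph",Ph,,135 ± 20,16%,1%,1%
19al,,II,NHPh,"3,5-Cl-Ph",Ph,,8%,1%,4%,1%
19am,,II,NHMe,"3,5-MeO-Ph",Ph,,11.0 ± 0.80,11.5 ± 4.7,60.0 ± 5.1,2%
19an,ISAM-CV247,II,NHPh,"3,5-MeO-Ph",Ph,,10%,17.3 ± 1.9,64.0 ± 9.6,1%
19ao,ISAM-CV202,II,NHMe,"3,4-OCH2O-Ph",Ph,,6.11 ± 0.60,14%,16%,17%
19ap,,II,NHEt,"3,4-OCH2O-Ph",Ph,,6.70 ± 0.67,894 ± 42,217 ± 18,1%
19aq,,II,NHPh,"3,4-OCH2O-Ph",Ph,,11.4 ± 3.7,28.0 ± 9.6,188 ± 23,25%
19ar,,II,NHMe,"3,4,5-MeO-Ph",Ph,,11.7 ± 3.1,3.63 ± 0.88,1%,15%
19as,,II,NHPh,"3,4,5-MeO-Ph",Ph,,76.5 ± 9.1,15.8 ± 3.7,1%,20%
19at,,II,NHMe,2-furyl,Ph,,6.66 ± 2.4,401 ± 25,51%,4%
19au,,II,NHPh,2-furyl,Ph,,33.7 ± 7.3,2.15 ± 0.11,14.7 ± 4.9,4%
19av,,II,NHMe,2-thienyl,Ph,,18%,25%,9%,1%
19aw,,II,NHPh,2-thienyl,Ph,,42.3 ± 4.6,330 ± 27,1%,3%
19ax,,II,NHMe,3-furyl,Ph,,1%,23%,1%,1%
19ay,,II,NHPh,3-furyl,Ph,,2%,368 ± 36,14%,2%
19az,ISAM-CV224,II,NHMe,3-thienyl,Ph,,42.8 ± 3.7,26%,51%,1%
19ba,ISAM-CV267,II,NHPh,3-thienyl,Ph,,9%,102 ± 27,17%,22%
19bb,,II,NHMe,4-pyridyl,Ph,,56.9 ± 6.7,5%,12%,1%
19bc,,II,NHPh,4-pyridyl,Ph,,30%,17%,18%,12%
19bd,ISAM-CV227,II,NHMe,3-pyridyl,Ph,,19.3 ± 7.1,19%,13%,1%
19be,,II,NHEt,3-pyridyl,Ph,,11.8 ± 3.5,335 ± 18,1%,2%
19bf,ISAM-CV248,II,NHPh,3-pyridyl,Ph,,23%,27.1 ± 5.7,29.4 ± 4.0,17%
19bg,,II,NHMe,cHex,Ph,,2%,1%,1%,11%
19bh,,II,NHPh,cHex,Ph,,1%,1%,6%,3%
19bi,,II,NHMe,3-Cl-Ph,3-Cl-Ph,,6%,3%,1%,12%
19bj,,II,NHPh,3-Cl-Ph,3-Cl-Ph,,13%,12%,2%,16%
19bk,,II,NHMe,"3,5-Cl-Ph",3-Cl-Ph,,10%,1%,4%,11%
19bl,,II,NHPh,"3,5-Cl-Ph",3-Cl-Ph,,2%,4%,1%,9%
19bm,,II,NHMe,4-MeO-Ph,4-MeO-Ph,,2%,2%,7%,23%
19bn,,II,NHPh,4-MeO-Ph,4-MeO-Ph,,1%,2%,2%,1%
20a,,III,NMe2,Ph,Ph,,8%,1%,3%,9%
20b,,III,NMe2,3-Cl-Ph,Ph,,11%,2%,1%,2%
20c,,III,NMe2,4-F-Ph,Ph,,12%,2%,4%,1%
XAC,,ref,,,,CCCN1C(=O)N(CCC)c2[nH]c(-c3ccc(OCC(=O)NCCN)cc3)nc2C1=O,29.1 ± 7.7,1.0 ± 0.2,141 ± 26,91.9 ± 26.1
DPCPX,,ref,,,,CCCN1C(=O)N(CCC)c2[nH]c(C3CCCC3)nc2C1=O,2.20 ± 0.17,157 ± 38,73.24 ± 5.18,1722 ± 112
ZM241385,,ref,,,,Nc1nc(NCCc2ccc(O)cc2)n2nc(-c3ccco3)nc2n1,683 ± 57,1.9 ± 0.27,65.7 ± 5.6,863 ± 37
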