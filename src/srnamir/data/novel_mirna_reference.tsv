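name	count	sequence	length	est_id	precursor_length	folding_energy
miR1	1099	GAGAUCAGAGAUGCACACAUUU	22	C20R5_004_B09	109	-47.3
miR1*	81	AUGUGUGGGUUUCUGGUCUCCA	22	C20R5_004_B09	109	-47.3
miR2	235	GAGAUCAGAUCAUGUGGCAGU	21	C20R5_011_B12	92	-33.6
miR3	5716	UUCCAUACAUCAUCUAUCUAAC	22	C20R5_011_C07	116	-53.2
miR4	9	GGUUCUAGAUCGACGGUGGCA	21	C20R5_013_G06	76	-21.9
miR5	12	UUGGUAGCGGCGAAGCAGGA	20	C20R5_029_G05	100	-43.2
miR6	37	CAGGACCGGUGGAGUGUUAUGC	22	C20R5_054_H07	84	-48.4
miR7	1481	UUAUUGUCGGACUAAGGUGUCU	22	HS018_G07	114	-49.1
miR7*	1	ACACUUAGUCUUGCGAUAACU	21	HS018_G07	114	-49.1
miR8	157	GACUAAUCUGUCGCGGAUCU	20	HS019_H02	270	-87.2
miR9	5280	GCUCAAGAAAGCUGUGGGAGA	21	HS049_E06	143	-51.2
miR10	9	GGGUUCUAGAUCGACGGUGGC	21	HS273_C01	246	-68.4
miR11	5	UGUAUGGUGGAUGUAGGCAUU	21	HS274_G03	161	-56.3
miR12	16	AAAGAUAACAUAUAACUCUGC	21	TFL_001_D10	117	-21.9
miR13	8	CAUACGAGUUGUAAGAAGAAU	21	TFL_007_A09	107	-32.2
miR14	25	GAGGAAGAGGAGGAUGAAGGCC	22	TFR6_007_H02	152	-67.7
miR15	9	AGAGCUCUCAACUACCGGAGA	21	TFR7_024_G09	106	-47.4
miR16	1100	AGAGAUCAGAGAUGCACACAUU	22	ES717218	131	-50.3
miR16*	82	UGUGUGGGUUUCUGGUCUCCA	21	ES717218	131	-50.3
miR17	5	UUGUUUGCGAGUUGGGAUUUU	21	ES721379	139	-58.1
miR18	37	UCGCAGGACCGGUGGAGUGUUA	22	ES718804	123	-58.8
miR19	8	CAAGUGGUCUGCUACUAAAUU	21	GO257540	146	-32.2
miR20	13	UGAAUACCUCAUUCGGCCUCU	21	GO259494	343	-74.6
miR21	9	CACUGUUAUCAAUGGGUGUAUCU	23	GO266079	97	-23.12
miR22	5	GCUUGGAAGGAUGUUAGAGUA	21	GO268464	75	-24
miR23	21	UGACUGAAGUAGGAGGGAAAU	21	GO267334	141	-63.4
miR24	28	GGAGUGAAACUGAGAACACAAA	22	GO324297	151	-59.8
miR25	26	UAGGCUUAUGACCUCUUUCCA	21	GO325945	188	-65.1
miR25*	6	GAAAGAGUUUAUAAGCCUACU	21	GO325945	188	-65.1
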