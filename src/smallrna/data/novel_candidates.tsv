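Name	Sequence	Arm	Length	Location	Precursor length (nt)	MFE	Count
miRNA-01	AAAGGGGACAGCTCACAGGATT	5′	22	chr4:16229484:16229558:+	75	−22.2	9
miRNA-02	AAATGAATCATGTTGGGCCTGT	3′	22	chr10:115051380:115051452:-	73	−53.8	10
miRNA-03	AACAAGAGAGCAGAACGAGGTT	5′	22	chr6:6152172:6152250: −	79	−22.5	32
miRNA-04	AAGGTAGCGGGAGGGTTGGGCT	3′	22	chr3:45883723:45883820:+	98	−40.5	8
miRNA-05	ACTGGCAAAAGGGTTTAGAACT	5′	22	chr16:50830166:50830246:+	81	−20.34	30
miRNA-06	AGAGGAGGGTGGAGCAAGTGGT	5′	22	chr2:68622734:68622824:+	91	−31.8	40
miRNA-07	AGCAGAGACGTTGGAACTGGGCT	5′	23	chr1:150534435:150534511: −	77	−28.6	8
miRNA-08	CATGGCACTGGAGTAGAGCAT	3′	21	chr8:141181858:141181951: −	94	−33.5	14
miRNA-09	CCCTGGGGTTCTGAGGACATG	5′	21	chr9:35710651:35710743: −	93	−39	711
miRNA-10	GAGAGCTCCGACTGCAGCTGC	3′	21	chr11:133027217:133027311: −	95	−35.3	20
miRNA-11	GAGGACCCTGCAGGAATGGACG	5′	22	chr11:122650500:122650575:+	76	−33.7	10
miRNA-12	GATGAGGAGGATGAGGAGGATG	5′	22	chr6:3616133:3616211:+	79	−21.7	14
miRNA-13	GGAGGAACCTTGGAGCTTCGGCA	3′	23	chr22:31556037:31556127: −	91	−45.3	70
miRNA-14	TAAGCATGCTGTCTTTCTGGAG	3′	22	chr15:28518177:28518257: −	81	−20.8	7
miRNA-15	TAGGCCATTTTGGAAGCTGTTT	5′	22	chr2:33498389:33498471:+	83	−23	19
miRNA-16	TCAGGCCAGGCTGGGAGGATGC	5′	22	chr1:55784355:55784424:+	70	−52.4	8
miRNA-17	TCCTGGAGCTGGGCAGATGGGA	5′	22	chr19:2762628:2762702: −	75	−35.7	5
miRNA-18	TCCTGTACTGAGCTGCCCCGAGC	5′	23	chr8:41517952:41518035:+	84	−59.1	18
miRNA-19	TCGACTTGCTCGGGCCCGGCT	3′	21	chr10:104402512:104402584: −	73	−34	15
miRNA-20	TCGGGCGGGAGTGGTGGCTTTT	3′	22	chr6:28918819:28918903:+	85	−22.2	233
miRNA-21	TGGGCAGGGGCTTATTGTAGGAGT	5′	24	chr6:32137807:32137893: −	87	−30.1	97
miRNA-22	TGGGGCTGCGGTGGGTCGGGA	3′	21	chr21:45209209:45209298: −	90	−46.6	27
miRNA-23	TTGAGGGGAGAATGAGGTGGAGA	5′	23	chr1:43830309:43830391: −	83	−33.5	11
miRNA-24	TTGCTGGGAAAGGGAGAAGTTCAT	3′	24	chr8:1703286:1703370: −	85	−46.8	8
miRNA-25	TTGGAGGGTGTGGAAGACAT	5′	20	chr19:13051290:13051374:+	85	−31	10
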