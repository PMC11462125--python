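taxon_group	locus	forward_name	forward_seq	reverse_name	reverse_seq	expected_len_min	expected_len_max	databases	forward_tail	reverse_tail
Seed plants	ITS2	ITS_S2F	ATGCGATACTTGGTGTGAAT	ITS_S3R	GACGCTTCTCCAGACTACAAT	300	500	BOLD/NCBI	0	0
Seed plants	rbcL	rbcLa-F	ATGTCACCACAAACAGAGACTAAAG	rbcLajf634R	GAAACGGTCTCTCCAACGCAT	607	607	BOLD/NCBI	0	0
Ferns, Lycophytes	rbcL	rbcLa-F	ATGTCACCACAAACAGAGACTAAAG	rbcLajf634R	GAAACGGTCTCTCCAACGCAT	607	607	BOLD/NCBI	0	0
Ferns, Lycophytes	trnL-trnF	trnL.C_bryo	CGAAATTGGTAGACGCTGCG	trnFGAAf	ATTTGAACTGGTGACACGAG	350	950	BOLD/NCBI	0	0
Liverworts, Mosses, Hornworts	ITS2	ITS2.seqF	AACAACTCTCAGCAACGG	ITS.4bryo	TCCTCCGCTTAGTGATATGC	300	500	BOLD/NCBI	0	0
Liverworts, Mosses, Hornworts	rbcL	rbcLa-F	ATGTCACCACAAACAGAGACTAAAG	rbcLajf634R	GAAACGGTCTCTCCAACGCAT	607	607	BOLD/NCBI	0	0
Liverworts, Mosses, Hornworts	psbA-trnH	psbA501F	TTTCTCAGACGGTATGCC	trnHR	GAACGACGGGAATTGAAC	450	700	BOLD/NCBI	0	0
Lichen-forming fungi	ITS	ITS1-F	CTTGGTCATTTAGAGGAAGTAA	ITS4	TCCTCCGCTTATTGATATGC	450	700	BOLD/NCBI/UNITE	0	0
Lichen-forming fungi	nuLSU	LROR	ACCCGCTGAACTTAAGC	LR5	ATCCTGAGGGAAACTTC	800	1000	BOLD/NCBI/UNITE	0	0
Lichen-forming fungi	mtSSU	mrSSU1	AGCAGTGAGGAATATTGGTC	mrSSU2R	CCTTCGTCCTTCAACGTCAG	650	900	BOLD/NCBI/UNITE	0	0
Arthropoda, Mollusca	COI	LCO1490	GGTCAACAAATCATAAAGATATTGG	HCO2198	TAAACTTCAGGGTGACCAAAAA ATCA	710	710	BOLD/NCBI	0	0
Arthropoda, Mollusca	COI	Lep_F1	ATTCAACCAATCATAAAGATATTGG	Lep_R1	TAAACTTCTGGATGTCCAAAAA ATCA	648	648	BOLD/NCBI	0	0
Gastropods	16S	16SAR_gpd_S	CGCCTGTTTAWCAAAAACAT	16SBR_gpd_S	CCGGTYTGAACTCAGATCAGAT CAYGT	570	570	BOLD/NCBI	0	0
Vertebrates	CO1	LepF1_t1	TGTAAAACGACGGCCAGTAT TCAAC CAATCATAAAGATATTGG	LepR1_t1	CAGGAAACAGCTATGACTAAAC TTC TGGATGTCCAAAAAATCA	700	700	BOLD/NCBI	18	17
Vertebrates	CO1	VF1_t1	TGTAAAACGACGGCCAGTTCT CAAC CAACCACAAAGACATTGG	VR1d_t1	CAGGAAACAGCTATGACTAGAC TTC TGGGTGGCCRAARAAYCA	700	700	BOLD/NCBI	18	17
Vertebrates	CO1	VF1d_t1	TGTAAAACGACGGCCAGTTCT CAAC CAACCACAARGAYATYGG	VR1_t1	CAGGAAACAGCTATGACTAGAC TTC TGGGTGGCCAAAGAATCA	700	700	BOLD/NCBI	18	17
Vertebrates	CO1	VF1i_t1	TGTAAAACGACGGCCAGTTCT CAAC CAACCAIAAIGAIATIGG	VR1i_t1	CAGGAAACAGCTATGACTAGAC TTC TGGGTGICCIAAIAAICA	700	700	BOLD/NCBI	18	17
Amoebozoa, Alveolata, Cercozoa, Chlorophyta, Cryptophyta, Euglenozoa	18S-V4	TAReuk454FWD1	CCAGCASCYGCGGTAATTCC	TAReukREV3	ACTTTCGTTCTTGATYRA	417	417	SILVA/PR2/NCBI	0	0
Amoebozoa, Alveolata, Cercozoa, Chlorophyta, Cryptophyta, Euglenozoa	18S-V4	E572F	CYGCGGTAATTCCAGCTC	E1009R	CRAAGAYGATYAGATACCRT	440	440	SILVA/PR2/NCBI	0	0
Amoebozoa, Alveolata, Cercozoa, Chlorophyta, Cryptophyta, Euglenozoa	18S-V9	1389F	TTGTACACACCGCCC	1510R	CCTTCYGCAGGTTCACCTAC	170	170	SILVA/PR2/NCBI	0	0
Amoebozoa, Alveolata, Cercozoa, Chlorophyta, Cryptophyta, Euglenozoa	18S-V9	1391F	GTACACACCGCCCGTC	EUKBr	TGATCCTTCTGCAGG TTCACCTAC	170	170	SILVA/PR2/NCBI	0	0
Ochrophyta	18S-V4	TAReuk454FWD1	CCAGCASCYGCGGTAATTCC	TAReukREV3	ACTTTCGTTCTTGATYRA	417	417	SILVA/PR2/NCBI	0	0
Ochrophyta	18S-V4	E572F	CYGCGGTAATTCCAGCTC	E1009R	CRAAGAYGATYAGATACCRT	440	440	SILVA/PR2/NCBI	0	0
Ochrophyta	18S-V4	D512	TTGTACACACCGCCC	D978rev	GACTACGATGGTATCTAATC	400	400	SILVA/PR2/NCBI	0	0
Ochrophyta	18S-V9	1389F	TTGTACACACCGCCC	1510R	CCTTCYGCAGGTTCACCTAC	170	170	SILVA/PR2/NCBI	0	0
Ochrophyta	18S-V9	1391F	GTACACACCGCCCGTC	EUKBr	TGATCCTTCTGCAGGTTCACCT AC	170	170	SILVA/PR2/NCBI	0	0
Fungi	ITS	ITS1F	CTTGGTCATTTAGAGGAAGTAA	ITS4	TCCTCCGCTTATTGATATGC	500	500	NCBI/UNITE	0	0
Phaeophytes	COI	GazF2	CCAACCAYAAAGATATWGGTAC	GazR2	GGATGACCAAARAACCAAAA	700	700	BOLD/NCBI	0	0
Phaeophytes, Rhodophytes	COI	GWSFn	TCAACAAAYCAYAAAGATATYGG	GWSRx	ACTTCTGGRTGICCRAARAAYCA	700	700	BOLD/NCBI	0	0
Phaeophytes, Rhodophytes	LSU D2/D3	T16N	AMAAGTACCRYGAGGGAAAG	T24U	SCWCTAATCATTCGCTTTACC	200	200	BOLD/NCBI	0	0
Rhodophytes	rbcL	rbcLa-F	ATGTCACCACAAACAGAGACTAAAGC	rbcLa-R	GTAAAATCAAGTCCACCRCG	500	500	BOLD/NCBI	0	0
Rhodophytes	rbcL	F57	GTAATTCCATATGCTAAAATGGG	rbcLrevNEW	ACATTTGCTGTTGGAGTYTC	1300	1300	BOLD/NCBI	0	0
Rhodophytes	rbcL	F57	GTAATTCCATATGCTAAAATGGG	TLR1	AAYTCWGCTCTTTCRTAYAT	650	650	BOLD/NCBI	0	0
Rhodophytes	rbcL	F57	GTAATTCCATATGCTAAAATGGG	TLR4	AAYTCWGCCCTTTCRTACAT	650	650	BOLD/NCBI	0	0
Rhodophytes	rbcL	AcroF1	AGCTCAAGCCGCAGCAGGAG	rbcLrevNEW	ACATTTGCTGTTGGAGTYTC	650	650	BOLD/NCBI	0	0
Rhodophytes	rbcL	TLF1	TCYCARCCWTTYATGCGCTGG	rbcLrevNEW	ACATTTGCTGTTGGAGTYTC	650	650	BOLD/NCBI	0	0
Rhodophytes	rbcL	M13LF3	TGTAAAACGACGGCCAGTACH AAYCAYAARGATATHGG	M13RX	CAGGAAACAGCTATGACACTTC TGGRTGICCRAARAAYCA	1300	1300	BOLD/NCBI	18	17
Chlorophyte macroalgae	tufA	tufGF4	GGNGCNGCNCAAATGGAYGG	tufAR	CCTTCNCGAATMGCRAAWCGC	600	600	BOLD/NCBI	0	0
Chlorophyte macroalgae	rbcL	GrbcLFi	TCTCARCCWTTYATGCGTTGG	1385R	AATTCAAATTTAATTTCTTTCC	650	650	BOLD/NCBI	0	0
Alismatales (seagrasses)	ITS	P674	CCTTATCATTTAGAGGAAGGAG	P675	TCCTCCGCTTATTGATATGC	700	700	BOLD/NCBI	0	0
Cryptophytes	psaA	psaA.F529	GGWTGGTTYCAYTAYCAYAARKCWGC	psaA.1748R	CCCAWGCHGAWMYTTGRCAW GTWCC	1050	1050	SILVA/PR2/NCBI	0	0
Protists	18S-V4	E572F	CYGCGGTAATTCCAGCTC	E1009R	AYGGTATCTRATCRTCTTYG	450	450	SILVA/PR2/NCBI	0	0
Protists	18S-V9	1389F	TTGTACACACCGCCC	1510R	CCTTCYGCAGGTTCACCTAC	150	150	SILVA/PR2/NCBI	0	0
Marine fungi and lichens	ITS	ITS1F	CTTGGCATTTAGAGGAAGTAA	ITS4	TCCTCCGCTTATTGATATGC	500	500	NCBI/Species Fungorum/UNITE	0	0
Marine fungi and lichens	18S	NS1	GTAGTCATATGCTTGTCTC	FR1	AICCATTCAATCGGTAIT	1650	1650	NCBI/Species Fungorum/UNITE	0	0
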