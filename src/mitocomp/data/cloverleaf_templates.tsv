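# Cloverleaf tRNA templates: all-canonical Watson-Crick stems.
# Coordinates in the arms table are zero-based half-open.
# name	anticodon	anticodon_start	sequence	structure
tRNA-Ile	GAT	33	TATTTATTTCCATCTTCCAGTATGGTAGGATGAGATGTATCCTTTTTTTAACATTTGTTGTTAAATAAATAA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Gln	TTG	33	CTTACTAAGTAATTAAGAATAATTATCTGATGCTTGAGATCAGATTATATTTTTACAATAAATATAGTAAGG	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Met	CAT	33	CAAGCTAGAAGTTATACAATAAACTATTATGAACATTACATAATTAATAACCGCCATATGGTTATAGCTTGG	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Trp	TCA	33	CCGGGTTACTTTTAAACAAATAAAAATAAACATTCAAAGTTTATTTCCAGTAATTTATTTACTGAACCCGGA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Cys	GCA	33	AAAAGAAATCTAGAAAGTCATCTAGTTATCCAAGCATGGGATAAAAAGCAGATTATCAATCTGCTTCTTTTT	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Tyr	GTA	33	AATCTAATACTCTTTAGTATTAGAGTGGAAATGGTAAGTTTCCATAAACGTTTAACTTTAACGTTTAGATTG	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Leu(UUR)	TAA	33	AAACTATTTATTGCTGCATTACAATAATGCATGTAAATTGCATAAAGTGAGTATATTTAACTCAATAGTTTC	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Lys	CTT	33	ACTCGTTAAACATTGATCTACATGTTTTATCTTCTTTTGATAAATGTAGTCTTAAAGGTAGACTAACGAGTA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Asp	GTC	33	CGGGAACATTTTTGACAATAAAAAAGTCACAAAGTCTATGTGAATTATTGATTTATAAAATCAAGTTCCCGC	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Gly	TCC	33	CTTAACTTAGATCATATATTAGATCAATCGAGCTCCCCTCGATGTTATTACCATATAGAGGTAAAGTTAAGT	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Ala	TGC	33	TTGGAAATTTTCTCCCATACAAGAACAATTAAATGCATTAATTCTATACAAGTGGATTCCTTGTTTTCCAAA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Arg	TCG	33	GAAGAGGTTTAACTATAATAAGTTATTCTAGAGTCGTTCTAGAGGATATTGAATTGAAATCAATCCTCTTCG	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Asn	GTT	33	CAAACTCTCATTTCGTATTTTAAATTAGGATCTGTTTGATCCTTTTAGCAATACAATTTATTGCGAGTTTGA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Ser(AGN)	GCT	18	GTATACTACCGATCCAAAGCTATTGGATTATAGGTATATCTAAGATACCAGTATACT	(((((((....(((((.......)))))....(((((.......)))))))))))).
tRNA-Glu	TTC	33	ATGTAATTTATTTTGATTAAGAAATTGTCTGGTTTCGACAGACAGTTTCTTAATCAATCTAAGAATTACATC	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Phe	GAA	33	TAAGATTCGTCAAGTATATTTTTGAATTCGTTAGAACTACGAACTAAATTTTATTGAGAAAAATAATCTTAA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-His	GTG	33	ATTTTATAAATTAAATAATCATAATATTGGCTTGTGAGGCCAATTATGAATATACGAAATATTCATAAAATA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Thr	TGT	33	ATCAACAAGTATATAATTTACTATAGCACACACTGTTTGTGTGTAAAATAGTTAGCTAGACTATTGTTGATT	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Pro	TGG	33	AAAGTCTTCTTATTAAACTTTATAAATCGAAAATGGGTTTCGAACGAGTAATTTTAAAAATTACAGACTTTA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Ser(UCN)	TGA	33	AACAAACGAATTTATATGCATAAATGCATAACTTGAAGTTATGTATTATGCGAAACTATCGCATGTTTGTTA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Leu(CUN)	TAG	33	AATTTAGCCATCTACGAACATAGATATAATTAATAGTGAATTAACATAGAGCGTCTATAGCTCTCTAAATTA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
tRNA-Val	TAC	33	TGTAACAAAGACGACTTAAGTCGTCGCTCATAATACGTATGAGACCTAGAATATAATATATTCTTGTTACAA	(((((((..((((........)))).(((((.......)))))....(((((.......)))))))))))).
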