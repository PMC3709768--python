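>cattle
ATGATTAATGTAGGCAGTCTGGCTTTAGAAGAGCATGGAGATCCCCAAGTCAGAGTATTA
CAGGTACTCAAATCATATGCGATCGCCACGTTAACCATTCCGAATTTTTCTAGTGACACA
ACTATTCAGAAATTCCAGGATTCCGTTATATGGGGGGCGATGTATACTATGTGTGATAGT
AGCAACGAATTTGGAGCGGGCGGTCGAGGGCCGGGGACCTCCGAGGATGTACAAGCTCCC
TTTGGAGGCATCCTGCCTGGCGGCAGACAAGAGCTCGTTTCGCCGTATTTCGCGATCAAC
ATAGAGTCGAATGTCGAAACTCCAGATTGCACGGTCAAGTTAGAAGTCGACCCTGAGGGG
GGGGCGATCGAGCCTGACTACGAAGTCACCCTCAAGGGTGCTCACGTTATCAACCTCGGG
TTAACATTAGAACAGGCTTTGAGCCTTGCTATGCTCAACAATATTTTCCAAGCAGATCTC
CATGTTTCAACGGTTAGAGAACTACAGGAACGGAAGCTGGGATTCGGAGCCGACGGAACC
GAGAGCGCCGTACCTAACGGCACCGGGTACAAGAGAATTAAAAAAAGCTCAATGTTTAAT
GCAGTCGTGGAGGCTGATCTCTTAGGCCTGATTACGGGACTTCAGGGTAAGCTAGCAGAT
GTAGCCGCCAAAGCAGCCCTCAGTCAAGAATCAAATTCAATGGATAAATGCATCATCTTG
AGTCAGTTGGAAATAGGCATCGCGGCTAGTTATATGAACCACAAGATGGACGAGGGGAGG
TTTTCTGTCAGCGATATTAAACAGATAAAGGTCGGGAGTATCGAAGTGAAGCAAGATGAG
GGGGAGGATAAAAGAGATCCTACGATGCACGGGGAGATCGGCTTACAAGGATCACGAAAA
ACGGACGGAAATCTTAACTTAGGTACTGACTACAACGAGGGCTATGCTTTCGGTGTCCAG
GTGCCGCCGTCAAAATCGTATTATGGAATCGGTCAAGAAAGTTAA
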