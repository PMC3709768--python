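>F_1
ATGATTAATGTAGGCAGTCTGGCTTTAGAAGAGCATGGAGATCCCCAAGTCAGAGTATTA
CAGGTACTCAAATCATATGCGATCGCCACGTTAACCATTCCGAATTTTTCTAGTGACACA
ACTATTCAGAAATTCCAGGATTCCGTTATATGGGGGGCGATGTATACTATGTGTGATAGT
AGCAACGAATTTGGAGCGGGCGGTCGAGGGCCGGGGACCTCCGAGGATGTACAAGCTCCC
TTTGGAGGCATCCTGCCTGGCGGCAGACAAGAGCTCGTTTCGCCGTATTTCGCGATCAAC
ATAGAGTCGAATGTCGAAACTCCAGATTGCACGGTCAAGTTAGAAGTCGACCCTGAGGGG
GGGGCGATCGAGCCTGACTACGAAGTCACCCTCAAGGGTGCTCACGGTATCAACCTCGGG
TTAACATTAGAACAGGCTTTGAGCCTTGCTATGCTCAACAATATTTTCCAAGCAGATCTC
CATGTTTCAACGGTTAGAGAACTACAGGAACGGAAGCTGGGATTCGGAGCCGACGGAACC
GAGAGCGCCGTACCTAACGGCACCGGGTACAAGAGAATTAAAAAAAGCTCAATGTTTAAT
GCAGTCGTGGAGGCTGATCTCTTAGGCCTGATTACGGGACTTCAGGGTAAGCTAGCAGAT
GTAGCCGCCAAAGCAGCCCTCAGTCAAGAATCAAATTCAATGGATAAATGCATCATCTTG
AGTCAGTTGGAAATAGGCATCGCGGCTAGTTATATGAACCACAAGATGGACGAGGGGAGG
TTTTCTGTCAGCGATATTAAACAGATAAAGGTCGGGAGTATCGAAGTGAAGCAAGATGAG
GGGGAGGATAAAAGAGATCCTACGATGCACGGGGAGATCGGCTTACAAGGATCACAAAAA
ACGGACGGAAATCTTAACTTAGGTACTGACTACAACGAGGGCTATGCTTTCGGTGTCCAG
GTGCCGCCGTCAAAATCGTATTATGGAATCGGTCAAGAAAGTTAA
>F_2
ATGATTAATGTAGGCAGTCTGGCTTTAGAAGAGCATGGAGATCCCCAAGTCAAAGTATTA
CAGGTACTCAAATCATATGCGATCGCCACGTTAACCATTCCGAATTTTTCTAGTGACACA
ACTATTCAGAAATTCCAGGATTCCGTTATATGGGGGGCGATGTATACTATGTGTGATAGT
AGCAACGAATTTGGAGCGGGCGGCCGAGGGCCGGGGACCTCCGAGGATGTACAAGCTCCC
TTTGGAGGCATCCTGCCTGGCGGCAGACAAGAGCTCGTTTCGCCGTATTTCGCGATCAAC
ATAGAGTCGAATGTCGAAACTCCAGATTGCACGGTCAAGTTAGAAGTCGACCCTGAGGGG
GGGGCGATCGAGCCTGACTACGAAGTCACCCTCAAGGGTGCTCACGTTATCAACCTCGGG
TTAACATTAGAACAGGCTTTGAGCCTTGCTATGCTCAACAATATTTTCCAAGCAGATCTC
CATGTTTCAACGGTTAGAGAACTACAGGAACGGAAGCTGGGATTCGGAGCCGACGGAACC
GAGAGCGCCGTACCTAACGGCACCGGGTACAAGAGAATTAAAAAAAGCTCAATGTTTAAT
GCAGTCGTGGAGGCTGATCTCTTAGGCCTGATTACGGGACTTCAGGGTAAGCTAGCAGAT
GTAGCCGCCAAAGCAGCCCTCAGTCAAGAATCAAATTCAGTGGATAAATGCATCATCTTG
AGTCAGTTGGAAATAGGCATCGCGGCTAGTTATATGAACCACAAGATGGACGAGGGGAGG
TTTTCTGTCAGCGATATTAAACAGATAAAGGTCGGGAGTATCGAAGTGAAGCAAGATGAG
GGGGAGGATAAAAGAGATCCTACGATGCACGGGGAGATCGGCTTACAAGGATCACAAAAA
ACGGACGGAAATCTTAACTTAGGTACTGACTACAACGAGGGCTATGCTTTCGGTGTCCAG
GTGCCGCCGTCAAAATCGTATTATGGAATCGGTCAAGAAAGTTAA
>M_1
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
>M_2
ATGATTAATGTAGGCAGTCTGGCTTTAGAAGAGCATGGAGATCCCCAAGTCAAAGTATTA
CAGGTACTCAAATCATATGCGATCGCCACGTTAACCATTCCGAATTTTTCTAGTGACACA
ACTATTCAGAAATTCCAGGATTCCGTTATATGGGGGGCGATGTATACTATGTGTGATAGT
AGCAACGAATTTGGAGCGGGCGGCCGAGGGCCGGGGACCTCCGAGGATGTACAAGCTCCC
TTTGGAGGCATCCTGCCTGGCGGCAGACAAGAGCTCGTTTCGCCGTATTTCGCGATCAAC
ATAGAGTCGAATGTCGAAACTCCAGATTGCACGGTCAAGTTAGAAGTCGACCCTGAGGGG
GGGGCGATCGAGCCTGACTACGAAGTCACCCTCAAGGGTGCTCACGTTATCAACCTCGGG
TTAACATTAGAACAGGCTTTGAGCCTTGCTATGCTCAACAATATTTTCCAAGCAGATCTC
CATGTTTCAACGGTTAGAGAACTACAGGAACGGAAGCTGGGATTCGGAGCCGACGGAACC
GAGAGCGCCGTACCTAACGGCACCGGGTACAAGAGAATTAAAAAAAGCTCAATGTTTAAT
GCAGTCGTGGAGGCTGATCTCTTAGGCCTGATTACGGGACTTCAGGGTAAGCTAGCAGAT
GTAGCCGCCAAAGCAGCCCTCAGTCAAGAATCAAATTCAGTGGATAAATGCATCATCTTG
AGTCAGTTGGAAATAGGCATCGCGGCTAGTTATATGAACCACAAGATGGACGAGGGGAGG
TTTTCTGTCAGCGATATTAAACAGATAAAGGTCGGGAGTATCGAAGTGAAGCAAGATGAG
GGGGAGGATAAAAGAGATCCTACGATGCACGGGGAGATCGGCTTACAAGGATCACGAAAA
ACGGACGGAAATCTTAACTTAGGTACTGACTACAACGAGGGCTATGCTTTCGGTGTCCAG
GTGCCGCCGTCAAAATCGTATTATGGAATCGGTCAAGAAAGTTAA
>S_1
ATGATTAATGTAGGCAGTCTGGCTTTAGAAGAGCATGGAGATCCCCAAGTCAGAGTATTA
CAGGTACTCAAATCATATGCGATCGCCACGTTAACCATTCCGAATTTTTCTAGTGACACA
ACTATTCAGAAATTCCAGGATTCCGTTATATGGGGGGCGATGTATACTATGTGTGATAGT
AGCAACGAATTTGGAGCGGGCGGCCGAGGGCCGGGGACCTCCGAGGATGTACAAGCTCCC
TTTGGAGGCATCCTGCCTGGCGGCAGACAAGAGCTCGTTTCGCCGTATTTCGCGATCAAC
ATAGAGTCGAATGTCGAAACTCCAGATTGCACGGTCAAGTTAGAAGTCGACCCTGAGGGG
GGGGCGATCGAGCCTGACTACGAAGTCACCCTCAAGGGTGCTCACGTTATCAACCTCGGG
TTAACATTAGAACAGGCTTTGAGCCTTGCTATGCTCAACAATATTTTCCAAGCAGATCTC
CATGTTTCAACGGTTAGAGAACTACAGGAACGGAAGCTGGGATTCGGAGCCGACGGAACC
GAGAGCGCCGTACCTAACGGCACCGGGTACAAGAGAATTAAAAAAAGCTCAATGTTTAAT
GCAGTCGTGGAGGCTGATCTCTTAGGCCTGATTACGGGACTTCAGGGTAAGCTAGCAGAT
GTAGCCGCCAAAGCAGCCCTCAGTCAAGCATCAAATTCAATGGATAAATGCATCATCTTG
AGTCAGTTGGAAATAGGCATCGCGGCTAGTTATATGAACCACAAGATGGACGAGGGGAGG
TTTTCTGTCAGCGATATTAAACAGATAAAGGTCGGGAGTATCGAAGTGAAGCAAGATGAG
GGGGAGGATAAAAGAGATCCTACGATGCACGGGGAGATCGGCTTACAAGGATCACGAAAA
ACGGACGGAAATCTTAACTTAGGTACTGACTACAACGAGGGCTATGCTTTCGGTGTCCAG
GTGCCGCCGTCAAAATCGTATTATGGAATCGGTCAAGAAAGTTAA
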