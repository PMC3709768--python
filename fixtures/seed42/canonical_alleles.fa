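>F
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAGATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGTGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
GATACATTTGGCCTTAAGGGAGCAGAAAATCTAGACTTGGAGGCGGTCTCAGCCATCGTA
ATCCAGCTCCACAGCTGGAACCGCATGCAACCGAGTTACGACCTAGGCTCGGAAGAGTTG
GTCAATCACGTACCTTGGTGGCTGAGTATGGGTCCACAATGTAGAGTTAATGACACGGAC
AGTGTCAATGCAAACATGAGGTTTCTGAGTTTCAATCGCGGTGAAATGGTCGAGGCTCTA
CGCAATGTCCTCTCTATCGCTAGGTCGTGCCTTACTGGGGGTAAAACCCAATGTTCGCGT
CTAAACGAGAATAATCAGAGAGCGGACGCCATGGGGGAGACGACGGACTGCCTCGGCGGA
TTGAGCGCCCGTACTGTTTCCAAGTCGCTAATTATTGGGCAGAACGGCTGCGGCGAATTC
GAGTATATTCTCACCTCCTTAGAGCCAGAATTCACTAAAATGCGCCGGGTGGTATCATCC
TCTCAGCTAAAAGACCTTATTCCGTCCCTGGTTAGACGAGGGAGTGAGTGGCCGGGCGAA
AACGTGGGCCCAGTGTCCGGCGTAGTGAGGAAGCGATTTGCATCAGAGCACGAGTCTCGA
ACTCAGCGTGTAAAGCGGGCTTGCAGCGACAAGGCAGCATTGTGTACAAGCTACCAATTT
ACCGACAATCCGAAAAATCCACAATTTTTGGCAGCGACCGATCGGGTAATCAAGCTGGTA
GAATTTAAAAATATTATCCGTCAAGAGCTGAAGGGCGATGAGTAA
>M
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAGATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGTGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
GATACATTTGGCCTTAAGGGAGCAGAAAATCTAGACTTGGAGGCGGTCTCAGCCATCGTA
ATCCAGCTCCACAGCTGGAACCGCATGCAACCGAGTTACGACCTAGGCTCGGAAGAGTTG
GTCAATCACGTACCTTGGTGGCTGAGTATGGGTCCACAATGTAGAGTTAATGACACGGAC
AGTGTCAATGCAAACATGAGGTTTCTGAGTTTCAATCGCGGTGAAATGGTCGAGGCTCTA
CGCAATGTCCTCTCTATCGCTAGGTCGTGCCTTACTGGGGGTAAAACCCAATGTTCGCGT
CTAAACGAGAATAATCAGAGAGCGGACGCCATGGGGGAGACGACGGACTGCCTCGGCGGA
TTGAGCGCCCGTACTGTTTCCAAGTCGCTAATTATTGGGCAGAACGGCTGCGGCGAATTC
GAGTATATTCTCACCTCCTTAGAGCCAGAATTCACTAAAATGCGCCGGGTGGTATCATCC
TCTCAGCTAAAAGACCTTATTCCGTCCCTGGTTAGACGAGGGAGTGAGTGGCCGGGCGAA
AACGTGGGCCCAGTGTCCGGCGTAGTGAGGAAGCGATTTGCATCAGAGCACGAGTCTCGA
ACTCAGCGTGTAAAGCGGGCTTGCAGCGACAAGGCAGCATTGTGTACAAGCTACCGATTT
ACCGACAATCCGAAAAATCCACAATTTTTGGCAGCGACCGATCGGGTAATCAAGCTGGTA
GAATTTAAAAATATTATCCGTCAAGAGCTGAAGGGCGATGAGTAA
>S
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAGATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGTGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
GATACATTTGGCCTTAAGGGAGCAGAAAATCTAGACTTGGAGGCGGTCTCAGCCATCGTA
ATCCAGCTCCACAGCTGGAACCGCATGCAACCGAGTTACGACCTAGGCTCGGAAGAGTTG
GTCAATCACGTACCTTGGTGGCTGAGTATGGGTCCACAATGTAGAGTTAATGACACGGAC
AGTGTCAATGCAAACATGAGGTTTCTGAGTTTCAATCGCGGTGAAATGGTCGAGGCTCTA
CGCAATGTCCTCTCTATCGCTAGGTCGTGCCTTACTGGGGGTAAAACCCAATGTTCGCGT
CTAAACGAGAATAATCAGAGAGCGGACGCCATGGGGGAGACGACGGACTGCCTCGGCGGA
TTGAGCGCCCGTACTGTTTCCAAGTCGCTAATTATTGGGCAGAACGGCTGCGGCGAATTC
GAGTATATTCTCACCTCCTTAGAGCCAGCATTCACTAAAATGCGCCGGGTGGTATCATCC
TCTCAGCTAAAAGACCTTATTCCGTCCCTGGTTAGACGAGGGAGTGAGTGGCCGGGCGAA
AACGTGGGCCCAGTGTCCGGCGTAGTGAGGAAGCGATTTGCATCAGAGCACGAGTCTCGA
ACTCAGCGTGTAAAGCGGGCTTGCAGCGACAAGGCAGCATTGTGTACAAGCTACCGATTT
ACCGACAATCCGAAAAATCCACAATTTTTGGCAGCGACCGATCGGGTAATCAAGCTGGTA
GAATTTAAAAATATTATCCGTCAAGAGCTGAAGGGCGATGAGTAA
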