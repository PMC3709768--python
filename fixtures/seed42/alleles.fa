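>F_1
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAGATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGTGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
GATACATTTGGCCTTAAGGGAGCAGAAAATCTAGACTTGGAGGCGGTCTCAGCCATCGTA
ATCCAGCTCCACAGCTGGAACCGCATGCAACCGAGTTACGACCTAGGCTCGGAAGAGTTG
GTCAATCACGTACCTTGGTGGCTGAGTATGGGTCCACAATGTAGAGGTAATGACACGGAC
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
>F_2
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAAATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGCGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
GATACATTTGGCCTTAAGGGAGCAGAAAATCTAGACTTGGAGGCGGTCTCAGCCATCGTA
ATCCAGCTCCACAGCTGGAACCGCATGCAACCGAGTTACGACCTAGGCTCGGAAGAGTTG
GTCAATCACGTACCTTGGTGGCTGAGTATGGGTCCACAATGTAGAGTTAATGACACGGAC
AGTGTCAATGCAAACATGAGGTTTCTGAGTTTCAATCGCGGTGAAATGGTCGAGGCTCTA
CGCAATGTCCTCTCTATCGCTAGGTCGTGCCTTACTGGGGGTAAAACCCAATGTTCGCGT
CTAAACGAGAATAATCAGAGAGCGGACGCCATGGGGGAGACGACGGACTGCCTCGGCGGA
TTGAGCGCCCGTACTGTTTCCAAGTCGCTAATTATTGGGCAGAACGGCTGCGGCGAATTC
GAGTATATTCTCACCTCCTTAGAGCCAGAATTCACTAAAGTGCGCCGGGTGGTATCATCC
TCTCAGCTAAAAGACCTTATTCCGTCCCTGGTTAGACGAGGGAGTGAGTGGCCGGGCGAA
AACGTGGGCCCAGTGTCCGGCGTAGTGAGGAAGCGATTTGCATCAGAGCACGAGTCTCGA
ACTCAGCGTGTAAAGCGGGCTTGCAGCGACAAGGCAGCATTGTGTACAAGCTACCAATTT
ACCGACAATCCGAAAAATCCACAATTTTTGGCAGCGACCGATCGGGTAATCAAGCTGGTA
GAATTTAAAAATATTATCCGTCAAGAGCTGAAGGGCGATGAGTAA
>M_1
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
>M_2
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAAATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGCGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
GATACATTTGGCCTTAAGGGAGCAGAAAATCTAGACTTGGAGGCGGTCTCAGCCATCGTA
ATCCAGCTCCACAGCTGGAACCGCATGCAACCGAGTTACGACCTAGGCTCGGAAGAGTTG
GTCAATCACGTACCTTGGTGGCTGAGTATGGGTCCACAATGTAGAGTTAATGACACGGAC
AGTGTCAATGCAAACATGAGGTTTCTGAGTTTCAATCGCGGTGAAATGGTCGAGGCTCTA
CGCAATGTCCTCTCTATCGCTAGGTCGTGCCTTACTGGGGGTAAAACCCAATGTTCGCGT
CTAAACGAGAATAATCAGAGAGCGGACGCCATGGGGGAGACGACGGACTGCCTCGGCGGA
TTGAGCGCCCGTACTGTTTCCAAGTCGCTAATTATTGGGCAGAACGGCTGCGGCGAATTC
GAGTATATTCTCACCTCCTTAGAGCCAGAATTCACTAAAGTGCGCCGGGTGGTATCATCC
TCTCAGCTAAAAGACCTTATTCCGTCCCTGGTTAGACGAGGGAGTGAGTGGCCGGGCGAA
AACGTGGGCCCAGTGTCCGGCGTAGTGAGGAAGCGATTTGCATCAGAGCACGAGTCTCGA
ACTCAGCGTGTAAAGCGGGCTTGCAGCGACAAGGCAGCATTGTGTACAAGCTACCGATTT
ACCGACAATCCGAAAAATCCACAATTTTTGGCAGCGACCGATCGGGTAATCAAGCTGGTA
GAATTTAAAAATATTATCCGTCAAGAGCTGAAGGGCGATGAGTAA
>S_1
ATGTCCACCTTCGTACCGAATCATTACAAACATGACGCGAGTCCGGAATGGAGATCTGAC
GCCAATCCGGTCGGCATTAACATAATGCACTCCGAGTCAGGTGAAAATGATAGCATGTTC
ATTCTAAGAATGATTCCGAAGCTTGAGCACGACACCTGTCAAGAACTTTCTGGGAGTGCA
CGGATTAATAATTTCGGCGAGGGCGGGCGAGTATACCAGGTCTTTCATAGGTACGACGAG
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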