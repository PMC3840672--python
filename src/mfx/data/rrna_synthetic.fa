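>rrna_synthetic_18S synthetic stand-in rRNA reference sequence
CTGATCTTCGGCAGGAGAATTGACTCTAACACTACTCTAACACCCTCGTATATACACACTCTTCTTGGTC
CTGACAATTCGTTCGTCTTTAATCAGGCAGCTGATCTTCGGGCCTAGGCAGCCGATTCTCCTTTATCTTG
GATCCAAACCGCAAAACTCTCGATACTAAATAGGGAATGAATGCCCGTATACAAAGAATTTGGTGTTGAT
ATCCACAACGCGTCGGCAGTATACTCAGGAGAATATCTTATTTTAAAGTTAACCACTTGTAGCATGGTCA
ACGAATGTGTAGACTATCACGTATGTCTCGAACCAGTGGAAGCGGACACTGGACGGGACTCTTCATCCTG
GTTTGGATGGCATAGAGAACCGTCTTGTCGTATCCTCTAGTATAACCCCCCACTCTGTAACTTATGGCTA
TATGAAATGAGACGTTGGGTGGGACTCGGGTAGGATGTCGTAGATGCGCGTCCGTTCGGTATTGGATAGA
TTAGGCAAGAGATGCTAGATGTGAGAGAAAACTGACGGCTGAGCGCCGAGGTCGGGCGTCGTGCTTTTAT
CAATTGTTGCGGAGGAGGGCAGGAGTTAGTGTTAAAAGTTACCTAGGACAAAGGAAAACTTTGGAGTTTC
GGGCATCTCCTCCCTCCATCGAAGGGTTCGACATGCTCACCTCTACTCCGAGTGCAAGATGATCAGAGTC
GCGTCGAAAACGAGATATTTCAAAGGAACGCCCATGAGTTACGACGAAAGAAGGGTCTACAGGTACGCCT
TCATAGATCTCTGTGGACAGGGCTAATCTGCAAGAAGCACACAACTGCCCCCGTTTAGGATGGTCGCAAG
AAAGATTCAATCGCAGCCGTGACGACACATTTCCATTTCTTTATTCGAGGCCTGGAGGGTTAAGACTGAA
TTAGTAGCTCAGCATTTTTGTTGCACCCCACATAGGGTGCAACGGCTCTGGTTGGGGTAGGTAAGGCACC
GCAGGCTAGGGTATCGGCCTGCATCGAACCTTAGCTGCAAACGGCAGGGGTCTAGGTCTTAACCGAGGCC
TCCTAGTTGGAATCCCCCACCAATCGAGCATGTGAGCGCCTTTTTGCCATGCCATAAGTTAAGCACGTGG
ATCCGTCAGCCGTTTGCATCCACGCGGACCCGCGGGATGGATTGCCTGCATCGACTTGTATCCGAGTTGC
CCGAGAACATCACATACATCCACCATTTTATTACTACTCTAGGACCGGTTCGCTATTACGATGACTCTAG
GCTCTCCAACCGTGGCACAGATACTGGTGGCCGGGGGAGTTGAGTAGATGCGAGCCATCCGGTTGCGCTA
AGACAGCTGCGATGTAGCGTATTTAGGAGAACAATGTGCTCGGGTGTATGATGCAGAGCCTCCGTCGGGT
AACTCCAGTTGCCGGGTTCCTCCACATGGGCCAAGCGCATTTCATGCCGCTGTCGAAGAGGAAGTTCGAT
ATGTGGGGTATACTGTGACACCAGGATAAAAGTGTTTTTAGAAGACCACCCAGCAATGTCGGTCCTCCAG
GAACACCCTTCCGACGACGTAGCGTGAGTTCAGATCTTACCTGACTGTTAAAACACAATCCTTAACGGCC
TCAGCGACGCGGGAGAATCTTGGCCCCGCAGTGCTTCAGATTTCATGAAATCGCCGGAGATCTAAGACGC
AGCCTCTAGTCGGCCCATAGCTTTTTGCACGTGAGGGCTGCCATTCCGCCACATTTTTTCCCCGTGGAAC
AGCCCGTTAAGTCGTCCCGCCTTCGTGCTCTGGGCCACAAACCCCCTGAC
>rrna_synthetic_28S synthetic stand-in rRNA reference sequence
AGGAGCATCTTTAGAAGCGAGCTTTTGCCCTGTAAAGACTTTTTCCGGGTGATGGGAATGCCATGATTAC
TACTCGAGCCTTCTCGTTGGCGGAGTAGGCCTCAATGACCCTGGATTAGCCTCCTCGCAGGCACCTCACG
TGCACTTCGGCCAGTAGCTTATCGCAAAAGACCACAATATTGCGGACGCATGACCAAGGGACGGGAGGAT
ACCCCGGTCGGATCAAGCGGCCGACTAGGCCTCCTCGTTAATAAGATTGCCCATTTCAGATCGCGTCCGA
AAAAGCTGACCTCAATGGGTACTTTGCAAAGTGTGAGTAACTCAGGCGAGACGGAAGCGGAACCTCACCC
GACTATCTCTTCGTCACAGTATACTGCGACTTAGCTGGGCGACTGTTGCTGTCCCACATCCCCCCCTATT
TGATATTCTTACGGCAGTGGCCTGAACGTACGTTAGGAATTTTATCATCCGGTTACCTCAAAGTTTTGTC
CGGCTGTGCTGTTCGTTAGCGATGACACTTACGATCAATGAGGTTACTCAACCACGACTAACGTTATGAC
GAGGGATACGGCGATGCTACACTTGACAAGACCTCAGAGCTCTAGAAGACGAGGGCAATTCCACTACTGT
CATTTAATAAAGCGTAATGGCGCCATCTAACCATTGAACAGTCCCAATTTGTTTGCGTTTCACACTATCC
TGTGCTAGTTTCGTACAAGAGCTTGGAGATATTCATTTCACTTACAGTCTACTACCCCATGCCTAGGGAC
TTGGCCCAACAATGGAGAGAGATATTACCGAGGACATAGATTTCAGCTGGCCTTGCTACTGACGAAGAGG
CATGCCTCTCTAAAAACCATTGCGCCTATAAAATTATGCAAATACGCATAACGCGGTATAGAACGGGCAC
TTCTCAAGCCGTCTGCCCATCATAAGTACCTGACATGACTTCAGTCAACCATGAGATAATCACGCCAGCC
TATTGGGCATGCCCGTGATGGCTTACATAATGGTACAACCTTACTGTGAGTCCAAACTCAGACGTGACTT
CGTGTGAATAGGCGGAAACTTCTTTACGTTATTCTGCGTGTGGCCGCTGCCATTTGAATTGTATACAGTT
CTTGACTTCTCGTAGAAAGGAGGTTTGTGTTCGGCTCATCACGGGTTAAACCACTCTGTCGGGCAGCTAC
AATAGTAGTGGGTTCTCACAGACAATAGGGGGGCGGGGGCTGTGACGTGCGACTACAAGTATAGTCGTCT
TCGCGTGGTAGTTGTCAGAAAAAAGGATAGGAACCTTTCCGCACTAGCCCGTGGTTTAAGTCCAACACTT
GAGCGGGGCGATTCTCGGATGCCATCTTGTTACAGTGCACGATGGGAGGGGTAGGCGAACGTACCAGTTA
AGCAATGGATTTCACCCACGGTGACCGACCATCAATGGCTTGCTCTGTTGGAAGTGTGTTTGGACTGGCT
GAACTACTGGAGTAGTTCAGCCTAGGCAGTATCCCAAGGCCATCTAAACCAAGACAAACTCACCGGCCAG
TTAGGTACCTGGCCTTAAGGCACTGCGGTGATTCTAGGAGGGCAGCGTAGTCTATTTAGCCACAAAGGCC
TCTCTAGAAGCTCTTCGGATGCTTTGTTGTTCCGTATGCATCCCGTTTCAAGTTGCGGAATCCTCCCTTA
AGTGTGTTTCAGCGCATAAGGGTCCGTTCCGACGCCCTGCTTAGGCATTATATAAAGATGACCAATCGTA
AGATTCAGAAAGCGAGCGGCTAAGAGACATTTTCCCTAAACCGGAGGATAATCCCCCATACAGGCTTCTT
GCATCCCCAAAAATCGGAGAGTTGGACGTGACTGTCTAGCGCAATACGATACTCGGTAATTAACCTCGAC
ACGGCTGTAGAATGCTCGCGGTAGTAGTTAGATTCAGATGTTCACCTGCATATATCAGTGAACTCTCTGC
TTCCGTACGTATAAACGTTTTACGCAACTTCTAGGGCCCCGATGGAGCCTCAACAGCTGTTCGAGACGCC
CGGCGGTTACCGGTCGGTTGTCGAACGATGGGATATTGCCCACTTATCCAACACAGGAAATCTAACATGG
CGAGGTCGTGGGAAGGATGAAAACGCGGCCTTCCGTAGTGAAACCGATCCCGTAGGGTTCCCGCATAACG
CTCCGATACCAGCAACGCTCTAGTTTAGGAATTAGCTTTCTTTATCTATAATTTTGTAAATGAGTCATTT
CGACTGAACAATAACCTAAACTAGACTATACTATCGGGGAGCTCGAGCGCACTCCATCACTCTTCCTGAA
GCCATATTAGTTCTCCGTTTGGTCTAAATTTAGCAGTTCTGGAGTTCTAATAGGCTCGGTTCGTTCAGTT
TACATGCTCCTCTCCCCACAATGGGCGACGTGCCACGCCTAGCGCCCTCCATTCTGTTATTAACGTCCTA
GTCACGCTCATTTGGGGTAAATGTACCGGCTCCCGGGTAGTATATCACTCAAGGCACTATGAACCGACGT
CGGCGCTGTAGTAAGCTACACCGGCTTGGCAAAGTTGGTCCGCCTGGGAAGCTCGCTAGTCCTGAAGGCA
TGATGCTGACCACCAGCGAAGGTATGGCACGTTGCACGAGCATTTCTCGAAGGCCTTTGTGACGCTGGGA
CGAGACTGAATAACACATCGAGCAGAAGCAGGGTTACTCTTTTCGACATTTGGAGCAGGACATGTCTACA
GGGGTGCCAGAGTAAGCAGCACCTTTCGTCCTTATTACAGGAAGACCGCAATCTAATCCTGTAAAAGTTC
GGCTCTGAAAGCCTTCTCGATTATTGTTTCCTCATTTGGGTAAAACTCATCCATGGTCCTACTTCTGATT
CTATTCTCGGCAAGCACTCCGCCTTTGTCGACTTCAGGCGAATATAGTCTTCGGTATGTATTACTCGGGG
AGTAGTACAACTAGACGTATGCGCTCTTTAAGGTGCTCATATTGTTTGATGCTCGCGCATGTCAACGGTG
CAGGCGACTATTCAGAGGCATGAATCCATCGCAAGTATTCACCGCCCGAGCAAAAATAAAAGAAGCTTTA
CAAACGTTGGTTAATACCTATGGTAGGATCAAAGTCATACACGACTAATAAGGTGCGAGAGTGCCCTCGC
CCGCGGAAACTGTCGAGAGGGTATTTGGGAACAGGGTTAAACCGAGTTTTCTAGGGACAAACCAAGCAGA
TTCACAGACAAAACCCTGTGTTAACGACCATTTGAGTCACAGCGCCACCGAGGCACAGACTCTGATCGCA
CAGAGACGAAGCTTCCCTTTACTTGCCAAGCTAGGGTTACCCTGGTCTCGCGCGGGTTGGCTAAAGTAAA
TTACCTATCTAAGCTTAACCCTTAGGATGGGTGGTTCGAG
>rrna_synthetic_5_8S synthetic stand-in rRNA reference sequence
CATCGGTGGTTTCTTACTGTGAAAGCGAGGTAGTGCTAGGTCATTAGCTCTCGGTCCCGGGTCGTCGTCG
GCCAGGCTGGGTAGGATATTGTGTGTGCCGAATATCCGCATGCTAGTTGTTGTAAGCTTCCGTGTAGGAC
GTGTCTTCGTAAGAGTATGG
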