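>MSL1/1
GACCTAGGTACAGAAAATGTCCCCAATGAAATGAATGAAGTAGAAATATCAGCCGAAGCAGTGGAAGAGAAGATGTCAGATTGCCATGTGGATATGGAGACTGGTGTAGATGCTAACCCTAGTAACGGATCTGAA
>MSL1/2
GGTGTTCTAAATGAAGGTGTTGTTTTCTCCTCCGAAGTCTGTAGCAAGATAGAAGACTTTACAGTTAACGTGAAAACCCAACCTCAACAAGAGACAAGATAATCATCTTAGGTAATTTATACCCTCATGATAATA
>MSL2/1
GTCCTTAAAGTCCACGCATAGTCTTCACTTGTTTTTAGCCTTGGGTTCAATGACCAAGTTTGATATCCAATCCGTGAACTTCACCTTTTCTACTATATCGGACTTGATCAATTTGTTTATTTTTTCTTCAATGAT
>MSL2/2
GGGCACGGAGTACTAGAGCTCATGACCCTAGATTTTGAACCAGCATCGGTACCAATTAATAACCCTTGGGATGAAGAACCGACCCTCCTCCCTCATGAAGACCTTGTTAAAGTGTCCATCCACCCAACCATTAAG
>MSL3/1
GTCCTTCTCTGCATATTGACCGCCACGGCGGTGGTCTGGAAGCCTTAGCAGTAGGCTGCTTTTCAAAATTTGGCCCTTATGTTTGTTTTCTTATCGTTCTTCCACCATTCTTGATCTGATTTGATTGTTTATGAT
>MSL3/2
GGATTGGATTATTCACCAACAAAGCTCATAACTTAAACCATAAAGGTATAGGATATCCATATGTCAGATTGGGTTCCACTCTCCACTAATGTAGGCTTAGAAATTCAAAAAGATCAAAAGGACATGGATCGGTTT
>MSL4/1
GTCCCTTGATCTGCAAAAAGTAGACAGAGCCAACCAACAGGAAAAATTAAATAAATTAGTTGTGGTGAGAAATTCCCGATCAAGCAGCCATTGCTAGCGCTAGGATGCTTGAATCTTCATTCAAGCAGTCAGATT
>MSL4/2
GGTCGTTATTATTAAATATTTTATTTTTCTGTGTGATTAGCTTTTAGATGAATTGTGGGGCTCAAACTTCATGATTCATCTCAATGCTTTCTGAGCTTCTCGATCTTTTCTTCATGTTTTTTCATGGTTGAAGAG
>MSL5/1
GTCCCTTCCAAAGGAGATGAGAGAATAGGATATTTATAGGAAAAATATCTAAACAAAATATCTAATCTGTGCAGAGGTCACCGCCGCGGCGGTGAGTAGGTCGGTTGGTTGATCGCCTCAGCGGTGAAAAAGACG
>MSL5/2
GGTTTTGTTAAGTTTTAGAGCATTTTTATATGTTTTAATTAGTTTTTATTCTTTTTGTATTAAAATAGGTGTATGGGGCTAAAATATAGGAAACTTGAGCGAAAACATTGAGATCGAACCAAAACGGTCGAAGAA
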