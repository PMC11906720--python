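>miR29B2C
GTAAATATATACGTGGGGGAAGAAGGGATAGCCATCGTCAGCAGTGGGCAACACTGTATCGTAGGGAAGCCTAGAAAAAGGGGGAAATTGGGATGAATGTTTTAGAATTTGGTTTTATTA
>FHL2
TGTTTTTCGGGTTTTGGGAGTATAGAGACTCGGAAGCGATCCTAACGCCGGTGAGTCCACTGGGGATCTAAGACACGGCCTGCTTTCCATGTATCATACAGTTCCTCTCGACGTCAAATACCTATCATCCCTAAGGCGCACTGTGGAGATTGGAGAAGTTTTAGGACGTG
>TRIM59
TATCGGTGGTTTGGGGGAGAGTGTTTTCACCGACCCGTGGCGTCGCCATTCGGTGACCATTGGTGTTAATGCCCAGCACAATCCTAGATTCGTTGTTTCGGGAAGTCGTT
>ELOVL2
CGGTCGGGCGGCGATTTGTAAGATGGGGCGACAACGCCTACGTACGCCGAGAACCCGCATTCGTGGGGCATGAACCCAAGCCACGTATGACTAAGTCTCAACCGGAAAGCATAGTTGGGTTTCGGTGGGT
>KLF14
CGGTTTTCGGTTAAGTTATGTTTAATAGTAAGGGAACCTCCGGCATTTCAGCATCCCATGAGAATCATACATCCACAGAAAAACATCATCCAGAGGAATTTTTGGGTTGTAGTAG
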