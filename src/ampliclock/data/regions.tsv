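gene	chrom	start	end	primer_fwd	primer_rev	adapter_tail_fwd	adapter_tail_rev
miR29B2C	chr1	207823646	207823765	GTAAATATATAYGTGGGGGAAGAAGGG	TAATAAAACCAAATTCTAAAACATTC	TACACGACGCTCTTCCGATCT	GACGTGTGCTCTTCCGATCT
FHL2	chr2	105399252	105399421	TGTTTTTYGGGTTTTGGGAGTATAG	CACRTCCTAAAACTTCTCCAATCTCC	TACACGACGCTCTTCCGATCT	GACGTGTGCTCTTCCGATCT
TRIM59	chr3	160450149	160450258	TATYGGTGGTTTGGGGGAGAG	AACRACTTCCCRAAACAACRAATCTA	TACACGACGCTCTTCCGATCT	GACGTGTGCTCTTCCGATCT
ELOVL2	chr6	11044600	11044729	YGGTYGGGYGGYGATTTGTA	ACCCACCRAAACCCAACTAT	TACACGACGCTCTTCCGATCT	GACGTGTGCTCTTCCGATCT
KLF14	chr7	130734358	130734472	YGGTTTTYGGTTAAGTTATGTTTAATAGT	CTACTACAACCCAAAAATTCC	TACACGACGCTCTTCCGATCT	GACGTGTGCTCTTCCGATCT
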