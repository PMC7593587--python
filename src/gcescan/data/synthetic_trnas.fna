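>pyl_tRNA synthetic pyrrolysine tRNA, CTA (CUA) anticodon
GGCGGCATAGCTCAGATGGTAGAGCACTGGATTCTAAATCCAGTGTTGGTCCTTCGAATGGACCTGCCGCC
>sec_tRNA synthetic selenocysteine tRNA, TCA (UCA) anticodon, long variable arm
GGCGGCATAGCTCAGATGGTAGAGCACTGGATTTCAAATCCAGACGGTGGGACGTGGACGGTCCTTCGAATGGACCTGCCGCC
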