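>grdA_like_cds synthetic CDS with in-frame TGA and SECIS-like hairpin
ATGTCAGGAATAAAGCAAATGGGCATGATATTCGAGGGGATGATTAAGTCACAAAAGAAT
GCCAAACTCGGCTTCCGCGCTTACTACCCCGGGGGTATGCAGATCAAATGCGTTTGGGGA
TGGACAGAAGAGAAGCAGATACGTGAATGGCAGGGGTCGAAATCTCGACAAGATGCGCAA
TTCTGCATGTGGAGACATATCCAGAAGAACACTTGTGCAGTTGGTACCGGAACGTACTGG
TTCATGGCTGGGAAGGCGCCGGAGGAACAAACCTATGAGTCGCGAACAGAGCTGGTTAAC
TTCGCTCGTTGCACCCAAGGGTTTTGTCATAACCACCTTCCACTTTTTTCCCGTCTAGAA
TTGATATTGGACCTATGCAAGCAGGAGGACGGATGGGGTTGGTTTTGCTCAGATGATATG
TTCCCTATGCGCCATGGCTTCCGTATTGTTTGACAGGCAGGTCCTTCGAGGACCTGCCAG
ATGTCGCAACAGTACCTCGTCACTAAACAGCTCCAAAAACTGTTTCCCTACATATGTAGG
TTCCAACAATGGAACGACGGTGGGTGGGTCAAGGTGAATCACTGTTGGGTCAGGGATAAT
ATCCAGGTGATGTGGGAGTGGGTCACTTATTTCGAGGCTAGTCTCGGGTGCGGGTATTGC
GCCGGTCACGAATTTATGGCATACTTAATCTGTGAAGTGCACCAGGAAATACATACGATA
TCGTGGCATTTTACGTGGTGGGATCCAGATATAAAATGGCGATGGACGCACGTGTGCTTT
GTTTGTCAAGTGTTTCAGAATAGACACGATTGGGACCACGCCGAGCAGGCCTTTCACCAT
TATGAATTCTCCCTCCTCTACTTTGCTGTGGGCCATACTCCATGCGTATGGGCCACGGAG
GACTCCAATAAGAACTTTCAGATACACAATTAA
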