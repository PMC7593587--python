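# synthetic genetic-code table: pyl_readthrough
name pyl_readthrough
start ATG
start GTG
start TTG
stop TAA
stop TGA
readthrough TAG O
codon AAA K
codon AAC N
codon AAG K
codon AAT N
codon ACA T
codon ACC T
codon ACG T
codon ACT T
codon AGA R
codon AGC S
codon AGG R
codon AGT S
codon ATA I
codon ATC I
codon ATG M
codon ATT I
codon CAA Q
codon CAC H
codon CAG Q
codon CAT H
codon CCA P
codon CCC P
codon CCG P
codon CCT P
codon CGA R
codon CGC R
codon CGG R
codon CGT R
codon CTA L
codon CTC L
codon CTG L
codon CTT L
codon GAA E
codon GAC D
codon GAG E
codon GAT D
codon GCA A
codon GCC A
codon GCG A
codon GCT A
codon GGA G
codon GGC G
codon GGG G
codon GGT G
codon GTA V
codon GTC V
codon GTG V
codon GTT V
codon TAC Y
codon TAT Y
codon TCA S
codon TCC S
codon TCG S
codon TCT S
codon TGC C
codon TGG W
codon TGT C
codon TTA L
codon TTC F
codon TTG L
codon TTT F
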