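"""Translation under the standard bacterial code vs amber readthrough.

A CDS with an internal TAG is prematurely truncated under the standard
bacterial code (table bact11) but reads through as pyrrolysine (O) under
the amber-readthrough table — the signature of a recoded gene.
"""

import gcescan as g

cds = g.NucleotideSequence(id="demo", seq="ATGGCATTCTAGGGTAAACTGTAA")

bact11 = g.load_table("bact11")
pyl = g.load_table("pyl_readthrough")

truncated = g.translate(cds, bact11)
readthrough = g.translate(cds, pyl)

print(f"CDS ({len(cds)} nt): {cds.seq}")
print(f"standard bacterial code : {truncated.seq!r} "
      f"({len(truncated)} aa, stops at the internal TAG)")
print(f"amber readthrough (TAG>O): {readthrough.seq!r} "
      f"({len(readthrough)} aa, O = pyrrolysine at codon "
      f"{readthrough.seq.index('O')})")
print("The readthrough translation is 4 residues longer: the TAG codon was "
      "decoded as the 22nd amino acid instead of terminating the protein.")
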