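"""tRNA cloverleaf and SECIS stem-loop scanning.

Scans a synthetic genome for the pyrrolysine tRNA (CUA anticodon) and for
the SECIS-like hairpin downstream of the selenoprotein's in-frame TGA.
"""

import gcescan as g

contig, manifest = g.generate_genome({"seed": 42}, preset="pyl_complete")

hits = g.scan_trna(contig, ("CTA", "TCA"))
print(f"tRNA hits: {len(hits)}")
for h in hits:
    print(f"  {h.kind} tRNA at {h.start}-{h.end} ({h.strand}), anticodon "
          f"{h.anticodon} ({h.anticodon_rna}), {h.score}/21 stem bases "
          f"paired, variable arm {h.variable_arm_len} nt")
truth = manifest.implant_for("pyl_tRNA")
print(f"  manifest ground truth: {truth['start']}-{truth['end']} "
      f"({truth['strand']})")

inv = g.pipeline.analyze_genome([contig])
for h in inv.secis_hits:
    print(f"SECIS-like hairpin: stem {h.stem_len} bp, loop {h.loop_len} nt, "
          f"{h.offset_nt} nt after the in-frame TGA at genome position "
          f"{h.tga_pos}")
print("A cloverleaf with a CUA anticodon decodes amber codons as "
      "pyrrolysine; the hairpin right after a UGA marks it for "
      "selenocysteine insertion.")
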