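"""Readthrough-gene extension: fusion, gating predicate and coordinates."""

import numpy as np
import pytest

import gcescan as g
from gcescan.pathway import InventoryRow


def nt(s):
    return g.NucleotideSequence(id="c", seq=s)


SENSE = [c for c in g.codes.ALL_CODONS
         if c not in ("TAA", "TAG", "TGA") and c not in ("ATG", "GTG", "TTG")]


def make_cds(rng, n_up, n_down, mid="TAG", stop="TAA"):
    up = "".join(rng.choice(SENSE, size=n_up))
    down = "".join(rng.choice(SENSE, size=n_down))
    return "ATG" + up + mid + down + stop


class TestFindCandidates:
    def test_single_amber_fusion(self, bact11, pyl_table):
        rng = np.random.default_rng(0)
        contig = nt(make_cds(rng, 10, 9))
        first = g.find_orfs(contig, bact11, min_aa=1)
        events = [ev for ev in
                  g.find_readthrough_candidates(contig, first, pyl_table)
                  if ev.gene.strand == "+"]
        assert len(events) == 1
        ev = events[0]
        assert len(ev.gene.protein.seq) == 21  # M + 10 + O + 9
        assert ev.codon_index == 11
        assert ev.gene.protein.seq[11] == "O"
        assert ev.codon == "TAG" and ev.inserted_residue == "O"

    def test_hard_stop_genes_yield_nothing(self, bact11, pyl_table):
        rng = np.random.default_rng(1)
        contig = nt(make_cds(rng, 10, 9, mid="GCA", stop="TAA"))
        first = g.find_orfs(contig, bact11, min_aa=1)
        assert g.find_readthrough_candidates(contig, first, pyl_table) == []

    def test_extension_off_contig_sets_partial_flag(self, bact11, pyl_table):
        rng = np.random.default_rng(2)
        contig = nt("ATG" + "".join(rng.choice(SENSE, size=10)) + "TAG"
                    + "".join(rng.choice(SENSE, size=4)))
        first = g.find_orfs(contig, bact11, min_aa=1)
        events = g.find_readthrough_candidates(contig, first, pyl_table)
        assert len(events) == 1 and events[0].gene.partial_3prime

    def test_fusion_links_downstream_first_pass_gene(self, bact11, pyl_table):
        rng = np.random.default_rng(3)
        # downstream piece starts with an in-frame ATG so the first pass
        # calls it as its own gene
        down = "ATG" + "".join(rng.choice(SENSE, size=30))
        contig = nt("ATG" + "".join(rng.choice(SENSE, size=30)) + "TAG"
                    + down + "TAA")
        first = g.find_orfs(contig, bact11, min_aa=1)
        events = [ev for ev in
                  g.find_readthrough_candidates(contig, first, pyl_table)
                  if ev.gene.strand == "+"]
        assert len(events) == 1
        ev = events[0]
        assert ev.upstream_gene is not None and ev.downstream_gene is not None
        down_prot = ev.downstream_gene.protein.seq
        assert (ev.gene.protein.seq
                == ev.upstream_gene.protein.seq + "O" + down_prot)

    def test_opal_extension_emits_selenocysteine(self, bact11, sec_table):
        rng = np.random.default_rng(4)
        contig = nt(make_cds(rng, 12, 8, mid="TGA"))
        first = g.find_orfs(contig, bact11, min_aa=1)
        events = g.find_readthrough_candidates(contig, first, sec_table)
        assert len(events) == 1
        assert events[0].inserted_residue == "U"
        assert events[0].gene.protein.seq[13] == "U"


class TestManifestGroundTruth:
    def test_implanted_amber_gene_recovered_exactly(self, complete_genome,
                                                    bact11, pyl_table):
        contig, manifest = complete_genome
        first = g.find_orfs(contig, bact11)
        events = g.find_readthrough_candidates(contig, first, pyl_table)
        mttb = manifest.implant_for("mttB")
        match = [ev for ev in events
                 if ev.gene.start == mttb["start"] and ev.gene.end == mttb["end"]]
        assert len(match) == 1
        assert match[0].codon_index == mttb["recoded_codon_index"]
        assert match[0].gene.strand == mttb["strand"]

    def test_event_codon_rereads_as_amber(self, complete_genome, bact11,
                                          pyl_table):
        contig, _ = complete_genome
        first = g.find_orfs(contig, bact11)
        for ev in g.find_readthrough_candidates(contig, first, pyl_table):
            assert ev.gene.codon_at(contig, ev.codon_index) == "TAG"
            up = ev.upstream_gene
            tail = ev.gene.protein.seq[ev.codon_index + 1:]
            assert ev.gene.protein.seq == up.protein.seq + "O" + tail


class TestGatingPredicate:
    @staticmethod
    def rows(present):
        return {k: InventoryRow(spec_key=k, display_name=k,
                                status="present" if k in present else "absent")
                for k in ("pylB", "pylC", "pylD", "selA")}

    def test_full_cassette_triggers(self):
        assert g.requires_readthrough_pass(self.rows({"pylB", "pylC", "pylD"}))

    def test_missing_enzyme_blocks(self):
        assert not g.requires_readthrough_pass(self.rows({"pylC", "pylD"}))

    def test_empty_inventory_blocks(self):
        assert not g.requires_readthrough_pass({})
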