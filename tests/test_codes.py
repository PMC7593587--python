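"""Genetic-code tables, translation semantics and six-frame scanning."""

import numpy as np
import pytest

import gcescan as g
from gcescan.codes import PrematureStopError, TableIntegrityError, GeneticCodeTable

from oracles import six_frame_fragments

SENSE_CODONS = [c for c in g.codes.ALL_CODONS if c not in ("TAA", "TAG", "TGA")]


def nt(s):
    return g.NucleotideSequence(id="t", seq=s)


class TestTableIntegrity:
    def test_packaged_tables_partition_64_codons(self, bact11, pyl_table, sec_table):
        for table in (bact11, pyl_table, sec_table):
            roles = (list(table.codon_map) + list(table.stops)
                     + list(table.readthrough))
            assert sorted(roles) == sorted(g.codes.ALL_CODONS)
        assert bact11.stops == {"TAA", "TAG", "TGA"}
        assert bact11.starts == {"ATG", "GTG", "TTG"}
        assert pyl_table.readthrough == {"TAG": "O"}
        assert pyl_table.stops == {"TAA", "TGA"}
        assert sec_table.readthrough == {"TGA": "U"}

    def test_incomplete_table_rejected(self, bact11):
        broken = dict(bact11.codon_map)
        broken.pop("AAA")
        with pytest.raises(TableIntegrityError):
            GeneticCodeTable(name="broken", codon_map=broken,
                             stops=bact11.stops, readthrough={},
                             starts=bact11.starts)

    def test_table_text_round_trip(self, pyl_table):
        again = GeneticCodeTable.from_text(pyl_table.to_text())
        assert again == pyl_table


class TestTranslate:
    def test_standard_cds(self, bact11):
        assert g.translate(nt("ATGGCAAAATAA"), bact11).seq == "MAK"

    def test_amber_readthrough_emits_pyrrolysine(self, pyl_table):
        assert g.translate(nt("ATGTAGGCATAA"), pyl_table).seq == "MOA"

    def test_truncate_policy_stops_at_amber(self, bact11):
        assert g.translate(nt("ATGTAGGCATAA"), bact11, "truncate").seq == "M"

    def test_error_policy_raises(self, bact11):
        with pytest.raises(PrematureStopError):
            g.translate(nt("ATGTAGGCA"), bact11, "error")

    def test_trailing_star_policy(self, bact11):
        assert g.translate(nt("ATGTAA"), bact11, "trailing_star").seq == "M*"

    def test_ambiguous_codon_emits_x_not_skipped(self, bact11):
        assert g.translate(nt("ATGANAAAA"), bact11).seq == "MXK"

    def test_incomplete_trailing_codon_ignored_with_warning(self, bact11, caplog):
        with caplog.at_level("WARNING", logger="gcescan.codes"):
            out = g.translate(nt("ATGGCAAA"), bact11)
        assert out.seq == "MA"
        assert any("TRAILING_CODON" in r.message for r in caplog.records)

    def test_length_consistency(self, bact11):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = "".join(rng.choice(SENSE_CODONS, size=rng.integers(1, 40)))
            assert len(g.translate(nt(s), bact11).seq) == len(s) // 3

    def test_readthrough_equivalence_on_tag_free_cds(self, bact11, pyl_table):
        # amber readthrough must be invisible on CDS without internal TAG
        rng = np.random.default_rng(1)
        codons = [c for c in SENSE_CODONS]
        for _ in range(200):
            s = "".join(rng.choice(codons, size=rng.integers(10, 120)))
            assert (g.translate(nt(s), bact11).seq
                    == g.translate(nt(s), pyl_table).seq)


class TestSixFrame:
    def test_frame_peptide_lengths_for_20mer(self, bact11):
        rng = np.random.default_rng(4)
        s = "".join(rng.choice(SENSE_CODONS, size=7))[:20]
        frames = g.six_frame_translate(nt(s), bact11)
        assert len(frames) == 6
        for fid, frags in frames:
            assert sum(len(f.seq) for f in frags) <= 6
        fwd_total = {fid: sum(len(f.seq) for f in frags)
                     for fid, frags in frames}
        # before stop-splitting every offset holds floor((20-k)/3) = 6 codons
        assert all(fwd_total[f] <= 6 for f in ("+1", "+2", "+3"))

    def test_strand_symmetry(self, bact11):
        rng = np.random.default_rng(8)
        s = "".join(rng.choice(list("ACGT"), size=120))
        rc = g.reverse_complement(nt(s))
        fw = {fid: sorted(f.seq for f in frags)
              for fid, frags in g.six_frame_translate(nt(s), bact11)}
        rv = {fid: sorted(f.seq for f in frags)
              for fid, frags in g.six_frame_translate(rc, bact11)}
        for k in range(1, 4):
            assert fw[f"+{k}"] == rv[f"-{k}"]
            assert fw[f"-{k}"] == rv[f"+{k}"]

    def test_matches_brute_force_scan(self, bact11):
        rng = np.random.default_rng(3)
        s = "".join(rng.choice(list("ACGT"), size=300))
        mine = {fid: sorted(f.seq for f in frags)
                for fid, frags in g.six_frame_translate(nt(s), bact11)}
        oracle = {fid: sorted(frags)
                  for fid, frags in six_frame_fragments(s, bact11)}
        assert mine == oracle
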