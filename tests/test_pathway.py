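"""Classification against the packaged reference set, conservation scoring
and the completeness verdict."""

import numpy as np
import pytest

import gcescan as g
from gcescan.orfs import GeneCall
from gcescan.pathway import COMPLETENESS_COMPONENTS, PathwayInventory
from gcescan.recoding import RecodingEvent


def test_reference_set_contains_expected_genes(specs_by_key):
    expected = {"pylB", "pylC", "pylD", "pylS_N", "pylS_C", "mttB", "ramA",
                "mttC", "cutC", "cutD", "grdA_like", "selA", "selB", "selD",
                "bcct", "mtbB", "mtmB_like"}
    assert set(specs_by_key) == expected
    assert specs_by_key["mttB"].expects_recoding == "TAG>O"
    assert specs_by_key["grdA_like"].expects_recoding == "TGA>U"
    assert specs_by_key["mtbB"].query_only and specs_by_key["mtmB_like"].query_only
    ref = specs_by_key["mttB"].references[0]
    assert ref.seq[specs_by_key["mttB"].recoded_index] == "O"
    assert (specs_by_key["grdA_like"].references[0]
            .seq[specs_by_key["grdA_like"].recoded_index] == "U")


class TestClassification:
    def test_exact_copy_is_present_at_100(self, specs, specs_by_key):
        ref = specs_by_key["pylB"].references[0]
        rows = g.classify_pathway_genes([ref], specs)
        assert rows["pylB"].status == "present"
        assert rows["pylB"].best_identity_pct == 100.0
        assert all(r.status == "absent" for k, r in rows.items() if k != "pylB")

    def test_random_protein_matches_nothing(self, specs):
        rng = np.random.default_rng(9)
        junk = g.ProteinSequence(
            id="junk",
            seq="M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=299)))
        rows = g.classify_pathway_genes([junk], specs)
        assert all(r.status == "absent" for r in rows.values())
        # exhaustive check: no single gene alignment reaches its thresholds
        for s in specs:
            aln, _ = g.pathway.best_alignment_to_spec(junk, s)
            assert (aln.identity_pct < s.min_identity
                    or aln.coverage_pct < s.min_coverage)

    def test_partial_cassette_triggers_second_pass_with_partial_verdict(
            self, specs, specs_by_key):
        proteins = [specs_by_key[k].references[0] for k in ("pylB", "pylC", "pylD")]
        rows = g.classify_pathway_genes(proteins, specs)
        assert g.requires_readthrough_pass(rows)
        inv = PathwayInventory(genome_id="t", rows=rows).finalize()
        assert inv.verdict == "partial"
        assert {"pylS_N", "pylS_C", "pyl_tRNA", "mttB_recoding"} <= set(
            inv.missing_components)

    def test_threshold_monotonicity(self, specs, specs_by_key):
        # a slightly diverged pylC copy: lowering min_identity can only turn
        # genes present, never absent
        ref = specs_by_key["pylC"].references[0]
        query = g.mutate_protein(ref, 30.0, seed=3)
        import dataclasses
        for hi, lo in ((60.0, 35.0), (90.0, 60.0)):
            strict = [dataclasses.replace(s, min_identity=hi) for s in specs]
            lax = [dataclasses.replace(s, min_identity=lo) for s in specs]
            strict_rows = g.classify_pathway_genes([query], strict)
            lax_rows = g.classify_pathway_genes([query], lax)
            for key in strict_rows:
                if strict_rows[key].status == "present":
                    assert lax_rows[key].status == "present"


def make_event(protein_seq, codon_index, residue="O"):
    n = len(protein_seq)
    gene = GeneCall(contig_id="c", start=0, end=3 * (n + 1), strand="+",
                    table_name="pyl_readthrough",
                    protein=g.ProteinSequence(id="q", seq=protein_seq))
    return RecodingEvent(gene=gene, codon="TAG" if residue == "O" else "TGA",
                         codon_index=codon_index, inserted_residue=residue)


class TestConservation:
    def test_identical_downstream_is_conserved(self, specs_by_key):
        spec = specs_by_key["mttB"]
        ev = make_event(spec.references[0].seq, spec.recoded_index)
        rep = g.assess_post_stop_conservation(ev, spec)
        assert rep.conserved and rep.aligned_identity_pct == 100.0
        assert rep.window_aa == 50

    def test_random_downstream_not_conserved(self, specs_by_key):
        spec = specs_by_key["mttB"]
        rng = np.random.default_rng(13)
        ref = spec.references[0].seq
        i = spec.recoded_index
        shuffled = (ref[:i + 1]
                    + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                         size=len(ref) - i - 1)))
        rep = g.assess_post_stop_conservation(make_event(shuffled, i), spec)
        assert not rep.conserved
        assert rep.aligned_identity_pct < 40.0

    def test_window_truncated_at_gene_end(self, specs_by_key):
        spec = specs_by_key["mttB"]
        i = spec.recoded_index
        short = spec.references[0].seq[:i + 11]   # 10 residues after O
        rep = g.assess_post_stop_conservation(make_event(short, i), spec)
        assert rep.window_aa == 10
        assert rep.conserved and rep.aligned_identity_pct == 100.0

    def test_gene_ending_at_recoded_codon_is_degenerate(self, specs_by_key):
        spec = specs_by_key["mttB"]
        i = spec.recoded_index
        stub = spec.references[0].seq[:i + 1]
        rep = g.assess_post_stop_conservation(make_event(stub, i), spec)
        assert rep.degenerate and not rep.conserved and rep.window_aa == 0

    def test_mismatched_residue_rejected(self, specs_by_key):
        spec = specs_by_key["grdA_like"]
        ev = make_event(spec.references[0].seq.replace("U", "O"), 150, "O")
        with pytest.raises(ValueError):
            g.assess_post_stop_conservation(ev, spec)


class TestVerdictPatterns:
    def test_completeness_components_are_the_pyl_set(self):
        assert set(COMPLETENESS_COMPONENTS) == {
            "pylB", "pylC", "pylD", "pylS_N", "pylS_C", "pyl_tRNA",
            "mttB_recoding"}

    def test_no_trna_genome_is_partial_missing_only_trna(self):
        contig, _ = g.generate_genome({"seed": 11}, preset="pyl_no_trna")
        inv = g.pipeline.analyze_genome([contig])
        assert inv.verdict == "partial"
        assert inv.missing_components == ["pyl_tRNA"]

    def test_decoy_is_present_but_unrecoded(self, complete_inventory):
        row = complete_inventory.rows["mtmB_like"]
        assert row.status == "present"
        assert row.recoding is None
        assert row.note == "no conserved in-frame TAG"
        assert complete_inventory.rows["mtbB"].status == "absent"
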