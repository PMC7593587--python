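"""Synthetic-data generator: determinism, composition and ground truth."""


import numpy as np
import pytest

import gcescan as g
from gcescan.simulate import (PRESETS, STOP_GUARD, back_translate,
                              implant_protein, random_background)


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self):
        a, ma = g.generate_genome({"seed": 5}, preset="pyl_complete")
        b, mb = g.generate_genome({"seed": 5}, preset="pyl_complete")
        assert a.seq == b.seq
        assert ma.to_json() == mb.to_json()

    def test_different_seed_differs(self):
        a, _ = g.generate_genome({"seed": 5}, preset="negative")
        b, _ = g.generate_genome({"seed": 6}, preset="negative")
        assert a.seq != b.seq

    def test_background_gc_within_binomial_bound(self):
        n = 100_000
        bg = random_background(np.random.default_rng(1), n, 0.5)
        gc = (bg.count("G") + bg.count("C")) / n
        # binomial oracle: +-2 percentage points is ~13 SD at this n
        sd = float(np.sqrt(0.5 * 0.5 / n))
        assert abs(gc - 0.5) < 0.02
        assert abs(gc - 0.5) < 6 * sd

    def test_implant_coordinates_address_their_sequences(self, complete_genome):
        contig, manifest = complete_genome
        for imp in manifest.implants:
            sub = contig.seq[imp["start"]:imp["end"]]
            oriented = (sub if imp["strand"] == "+"
                        else g.sequences.revcomp_str(sub))
            if imp["spec_key"] in ("pyl_tRNA", "sec_tRNA"):
                continue
            assert oriented[:3] == "ATG"
            assert oriented[-3:] == "TAA"
            ridx = imp["recoded_codon_index"]
            if ridx is not None:
                codon = oriented[3 * ridx: 3 * ridx + 3]
                assert codon in ("TAG", "TGA")

    def test_implants_spaced_and_guarded(self, complete_genome):
        contig, manifest = complete_genome
        implants = sorted(manifest.implants, key=lambda i: i["start"])
        for a, b in zip(implants, implants[1:]):
            assert b["start"] - a["end"] >= 100
        for imp in implants:
            assert (contig.seq[imp["start"] - len(STOP_GUARD):imp["start"]]
                    == STOP_GUARD)

    def test_preset_no_trna_lists_no_trna_implant(self):
        _, manifest = g.generate_genome({"seed": 2}, preset="pyl_no_trna")
        assert manifest.implant_for("pyl_tRNA") is None
        assert set(PRESETS["pyl_no_trna"]) == set(PRESETS["pyl_complete"]) - {"pyl_tRNA"}

    def test_insufficient_length_raises_with_required_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            g.generate_genome({"seed": 0, "length_nt": 5000},
                              preset="pyl_complete")

    def test_manifest_round_trip(self, complete_genome, tmp_path):
        _, manifest = complete_genome
        path = tmp_path / "m.json"
        manifest.write(path)
        again = g.SyntheticManifest.read(path)
        assert again == manifest


class TestMutateProtein:
    def test_zero_divergence_is_identity(self):
        p = implant_protein("pylB")
        assert g.mutate_protein(p, 0.0, seed=1).seq == p.seq

    def test_full_divergence_changes_every_canonical_site(self):
        p = g.ProteinSequence(id="p", seq="M" + "A" * 99)
        out = g.mutate_protein(p, 100.0, seed=1)
        assert all(a != b for a, b in zip(p.seq, out.seq))

    def test_recoded_residues_never_mutated(self):
        p = g.ProteinSequence(id="p", seq="MOUAOU" * 20)
        out = g.mutate_protein(p, 100.0, seed=2)
        assert all(b == a for a, b in zip(p.seq, out.seq) if a in "OU")

    def test_substitution_count_matches_binomial(self):
        n, d, trials = 100, 0.05, 1000
        p = g.ProteinSequence(id="p", seq="A" * n)
        counts = [sum(a != b for a, b in zip(p.seq,
                                             g.mutate_protein(p, 100 * d, seed=k).seq))
                  for k in range(trials)]
        mean = float(np.mean(counts))
        se = float(np.sqrt(n * d * (1 - d) / trials))
        assert abs(mean - n * d) < 3 * se


class TestTranscripts:
    def test_backtranslation_round_trips_through_readthrough_table(self):
        p = implant_protein("mttB")
        rng = np.random.default_rng(0)
        cds = back_translate(p.seq, rng)
        table = g.load_table("pyl_readthrough")
        assert g.translate(g.NucleotideSequence(id="t", seq=cds), table).seq == p.seq

    def test_recoded_sites_backtranslate_to_stop_codons(self):
        rng = np.random.default_rng(0)
        cds = back_translate("MOU", rng)
        assert cds[3:6] == "TAG" and cds[6:9] == "TGA"

    def test_requires_implants(self):
        empty = g.SyntheticManifest(seed=0, genome_id="x")
        with pytest.raises(ValueError):
            g.simulate_transcripts(empty)

    def test_transcripts_recorded_in_manifest(self):
        _, manifest = g.generate_genome({"seed": 3}, preset="pyl_complete")
        tx, manifest = g.simulate_transcripts(manifest, per_gene=1,
                                              divergence_levels=[0.0],
                                              seed=4, spec_keys=["mttB", "bcct"])
        assert len(tx) == 2
        assert {t["spec_key"] for t in manifest.transcripts} == {"mttB", "bcct"}
        for rec in manifest.transcripts:
            assert rec["frame"] in ("+1", "+2", "+3", "-1", "-2", "-3")
        mttb = [t for t in manifest.transcripts if t["spec_key"] == "mttB"][0]
        assert mttb["covers_recoded_site"]
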