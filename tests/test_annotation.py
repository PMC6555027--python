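"""Gene-model I/O, lifting, spurious-intron collapse, frames, translation
and the transcript/protein sanity check."""

import dataclasses

import pytest

from majorref.annotation import (
    GeneModel,
    MalformedRowError,
    collapse_spurious_introns,
    extract_transcript,
    lift_gene_model,
    migrate_annotation,
    read_genepred,
    recompute_frames,
    sanity_check,
    translate_cds,
    write_genepred,
)
from majorref.liftover import OLD2NEW


def model(**kw):
    base = dict(name="tx1", chrom="chr1", strand="+", tx_start=0, tx_end=30,
                cds_start=0, cds_end=30, exon_starts=[0], exon_ends=[30],
                exon_frames=[0])
    base.update(kw)
    return GeneModel(**base)


class TestGenePredIO:
    def test_two_exon_row(self, tmp_path):
        p = tmp_path / "a.gp"
        p.write_text("tx\tchr1\t+\t0\t40\t5\t35\t2\t0,22,\t12,40,\t0\tG\t"
                     "cmpl\tcmpl\t0,1,\n")
        (m,) = read_genepred(p)
        assert m.exons() == [(0, 12), (22, 40)]
        assert m.exon_frames == [0, 1]
        assert m.bin is None

    def test_bin_column_preserved(self, tmp_path):
        p = tmp_path / "b.gp"
        p.write_text("9\ttx\tchr1\t-\t0\t40\t5\t35\t1\t0,\t40,\t0\tG\t"
                     "cmpl\tcmpl\t0,\n")
        (m,) = read_genepred(p)
        assert m.bin == 9
        out = tmp_path / "c.gp"
        write_genepred([m], out)
        assert out.read_text() == p.read_text()

    def test_roundtrip_fixpoint_on_generated_models(self, tmp_path,
                                                    scenario):
        p1 = tmp_path / "m1.gp"
        write_genepred(scenario.genes.models, p1)
        back = read_genepred(p1)
        p2 = tmp_path / "m2.gp"
        write_genepred(back, p2)
        assert p1.read_text() == p2.read_text()
        assert [m.name for m in back] == \
            [m.name for m in scenario.genes.models]

    def test_ragged_exons_malformed(self, tmp_path):
        p = tmp_path / "bad.gp"
        p.write_text("tx\tchr1\t+\t0\t40\t0\t40\t2\t0,22,\t12,\t0\tG\t"
                     "cmpl\tcmpl\t0,1,\n")
        with pytest.raises(MalformedRowError):
            read_genepred(p)


class TestFrames:
    def test_single_exon_cds(self):
        assert recompute_frames(model()).exon_frames == [0]

    def test_cumulative_mod_three(self):
        m = model(tx_end=40, cds_start=0, cds_end=40,
                  exon_starts=[0, 20], exon_ends=[5, 26],
                  exon_frames=[0, 0])
        # CDS lengths 5 then 6 -> frames [0, 5 mod 3 = 2]
        assert recompute_frames(m).exon_frames == [0, 2]

    def test_utr_only_first_exon(self):
        m = model(tx_end=60, cds_start=25, cds_end=55,
                  exon_starts=[0, 20, 40], exon_ends=[10, 30, 60],
                  exon_frames=[0, 0, 0])
        f = recompute_frames(m).exon_frames
        assert f[0] == -1 and f[1] == 0 and f[2] == (30 - 25) % 3

    def test_noncoding_all_minus_one(self):
        m = model(cds_start=0, cds_end=0)
        assert recompute_frames(m).exon_frames == [-1]

    def test_minus_strand_walks_in_transcription_order(self):
        m = model(strand="-", tx_end=40, cds_start=0, cds_end=40,
                  exon_starts=[0, 20], exon_ends=[5, 25],
                  exon_frames=[0, 0])
        # transcription order is exon2 (5 bases, frame 0) then exon1
        # (5 preceding CDS bases -> frame 5 mod 3 = 2)
        assert recompute_frames(m).exon_frames == [2, 0]

    def test_fixpoint(self, scenario):
        for m in scenario.genes.models:
            once = recompute_frames(m)
            assert recompute_frames(once).exon_frames == once.exon_frames


class TestTranslation:
    def test_plus_strand_simple(self):
        g = {"chr1": "ATGAAATAG"}
        m = model(tx_end=9, cds_end=9, exon_ends=[9])
        assert extract_transcript(m, g) == "ATGAAATAG"
        assert translate_cds(m, g) == "MK"

    def test_minus_strand_revcomp(self):
        # revcomp("CTACAT") == "ATGTAG" -> "M"
        g = {"chr1": "CTACAT"}
        m = model(strand="-", tx_end=6, cds_end=6, exon_ends=[6])
        assert extract_transcript(m, g) == "ATGTAG"
        assert translate_cds(m, g) == "M"

    def test_frame_offset_skips_bases(self):
        g = {"chr1": "CCATGAAATAG"}
        m = model(tx_end=11, cds_end=11, exon_ends=[11], exon_frames=[2])
        assert translate_cds(m, g) == "MK"

    def test_internal_stop_truncates(self):
        g = {"chr1": "ATGTAAAAATAG"}
        m = model(tx_end=12, cds_end=12, exon_ends=[12])
        assert translate_cds(m, g) == "M"


class TestLiftGeneModel:
    def test_model_upstream_of_edits_unchanged(self, toy_map):
        m = model(tx_start=0, tx_end=4, cds_start=0, cds_end=4,
                  exon_starts=[0], exon_ends=[4])
        lifted = lift_gene_model(m, toy_map, OLD2NEW)
        assert (lifted.tx_start, lifted.tx_end) == (0, 4)
        assert lifted.flags == ()

    def test_exon_spanning_deletion_shrinks(self, toy_map):
        # old base 5 is deleted; an exon over old 3-7 loses one base
        m = model(tx_start=3, tx_end=7, cds_start=3, cds_end=7,
                  exon_starts=[3], exon_ends=[7])
        lifted = lift_gene_model(m, toy_map, OLD2NEW)
        assert lifted.exons() == [(3, 6)]

    def test_exon_containing_insertion_grows(self, toy_map):
        # new gains 2 bases after old base 7
        m = model(tx_start=6, tx_end=10, cds_start=6, cds_end=10,
                  exon_starts=[6], exon_ends=[10])
        lifted = lift_gene_model(m, toy_map, OLD2NEW)
        assert lifted.exons() == [(5, 11)]


class TestCollapse:
    def test_zero_length_intron_merged(self):
        m = model(tx_end=30, cds_end=30, exon_starts=[10, 20],
                  exon_ends=[20, 30], tx_start=10, cds_start=10,
                  exon_frames=[0, 0])
        merged = collapse_spurious_introns(m)
        assert merged.exons() == [(10, 30)]
        assert any(f.startswith("merged_introns") for f in merged.flags)

    def test_short_real_intron_kept_at_default_threshold(self):
        m = model(tx_end=35, cds_end=35, exon_starts=[10, 25],
                  exon_ends=[20, 35], tx_start=10, cds_start=10,
                  exon_frames=[0, 0])
        assert collapse_spurious_introns(m).exons() == [(10, 20), (25, 35)]
        assert collapse_spurious_introns(m, merge_threshold=5).exons() == \
            [(10, 35)]


class TestSanity:
    def test_consistent_fixture_is_perfect(self, scenario, scenario_applied,
                                           scenario_map):
        _, _, new_genome, _ = scenario_applied
        migrated, unmapped = migrate_annotation(scenario.genes.models,
                                                scenario_map)
        assert unmapped == []
        rep = sanity_check(migrated, new_genome, scenario.genes.mrna,
                           scenario.genes.proteins)
        assert rep.mrna_match_pct == 100.0
        assert rep.protein_match_pct == 100.0
        # planted spurious introns actually exercised the merge path
        assert any("merged_introns=1" in m.flags for m in migrated)

    def test_merge_restores_reading_frame(self, scenario, scenario_applied,
                                          scenario_map):
        """Without the collapse + frame recomputation, transcripts whose
        exons were stitched across repaired insertions mismatch."""
        _, _, new_genome, _ = scenario_applied
        repaired = {v.vid.rsplit("_", 1)[0]
                    for v in scenario.genes.repair_variants}
        assert repaired
        lifted_only = []
        for m in scenario.genes.models:
            lifted_only.append(lift_gene_model(m, scenario_map, OLD2NEW))
        rep = sanity_check(lifted_only, new_genome, scenario.genes.mrna,
                           scenario.genes.proteins)
        # untouched genes still match even without the repair pass
        for m in lifted_only:
            if m.name not in repaired:
                assert rep.statuses[m.name][0] == "MATCH"

    def test_planted_mismatch_gives_75_pct(self, scenario, scenario_applied,
                                           scenario_map):
        _, _, new_genome, _ = scenario_applied
        migrated, _ = migrate_annotation(scenario.genes.models, scenario_map)
        four = migrated[:4]
        proteins = {m.name: scenario.genes.proteins[m.name] for m in four}
        proteins[four[0].name] = "M" + proteins[four[0].name][1:][::-1]
        mrna = {m.name: scenario.genes.mrna[m.name] for m in four}
        rep = sanity_check(four, new_genome, mrna, proteins)
        assert rep.protein_match_pct == 75.0

    def test_empty_model_list_reports_na(self):
        rep = sanity_check([], {}, {}, {})
        assert rep.n_transcripts == 0
        assert rep.as_dict()["mrna_match_pct"] == "NA"

    def test_absent_transcripts_skipped(self, scenario, scenario_applied,
                                        scenario_map):
        _, _, new_genome, _ = scenario_applied
        migrated, _ = migrate_annotation(scenario.genes.models, scenario_map)
        rep = sanity_check(migrated, new_genome, {}, {})
        assert all(s == "SKIPPED" for s, _ in rep.statuses.values())


def test_matching_transcripts_have_cds_multiple_of_three(scenario,
                                                         scenario_applied,
                                                         scenario_map):
    _, _, new_genome, _ = scenario_applied
    migrated, _ = migrate_annotation(scenario.genes.models, scenario_map)
    rep = sanity_check(migrated, new_genome, scenario.genes.mrna,
                       scenario.genes.proteins)
    for m in migrated:
        if rep.statuses[m.name][0] == "MATCH":
            assert sum(m.cds_exon_lengths()) % 3 == 0


def test_exon_lists_stay_sorted_after_every_operation(scenario,
                                                      scenario_map):
    for m in scenario.genes.models:
        lifted = lift_gene_model(m, scenario_map, OLD2NEW)
        merged = collapse_spurious_introns(lifted)
        final = recompute_frames(merged)
        for mm in (lifted, merged, final):
            assert mm.exon_starts == sorted(mm.exon_starts)
            assert all(s < e for s, e in mm.exons())
            assert all(a <= b for a, b in zip(mm.exon_ends,
                                              mm.exon_starts[1:]))
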