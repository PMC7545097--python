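"""Cross-link parsing, curation rules, residue mapping and collapse."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from talemap.proteinmodel import ProteinRecord
from talemap.xlink_core import (
    CrossLink,
    MappingError,
    PeptideIdentification,
    PlinkDialect,
    SpectrumAnnotation,
    aggregate_replicates,
    classify_link,
    collapse_redundant,
    curate_identifications,
    infer_peptide_offsets,
    longest_run,
    map_to_residues,
    parse_compact_notation,
    parse_plink_table,
)


def ident(**kw):
    defaults = dict(
        peptide_a="KTVLSIR", pos_a=1, protein_a="PBX1",
        peptide_b="SQTPMDVDKQAIYR", pos_b=9, protein_b="PREP1",
        residue_a=87, residue_b=55,
    )
    defaults.update(kw)
    return PeptideIdentification(**defaults)


class TestCompactNotation:
    def test_pair_row(self):
        rec = parse_compact_notation(
            "PBX1(87)-PREP1(55)", "KTVLSIR(1)-SQTPMDVDKQAIYR(9)")
        assert (rec.pos_a, rec.pos_b) == (1, 9)
        assert (rec.residue_a, rec.residue_b) == (87, 55)
        assert (rec.protein_a, rec.protein_b) == ("PBX1", "PREP1")

    def test_loop_row(self):
        rec = parse_compact_notation("PBX1 (85)(87)", "IKEKTVLSIR(2)(4)")
        assert rec.is_loop
        assert (rec.pos_a, rec.pos_b) == (2, 4)
        assert (rec.residue_a, rec.residue_b) == (85, 87)

    def test_non_lysine_position_rejected(self):
        with pytest.raises(ValueError, match="not K"):
            parse_compact_notation("PBX1(87)-PREP1(55)", "KTVLSIR(2)-SQTPMDVDKQAIYR(9)")

    def test_nterm_flag_accepts_position_one(self):
        rec = parse_compact_notation(
            "PBX1(81)-PREP1(55)", "AVLSIR(1)-SQTPMDVDKQAIYR(9)", allow_nterm=True)
        assert rec.pos_a == 1


class TestPlinkTable:
    HEADER = ("peptide_a\tpos_a\tprotein_a\tpeptide_b\tpos_b\tprotein_b\t"
              "residue_a\tresidue_b\tevalue\treplicate\n")

    def test_round_row(self, tmp_path):
        f = tmp_path / "ids.tsv"
        f.write_text(self.HEADER +
                     "KTVLSIR\t1\tPBX1\tSQTPMDVDKQAIYR\t9\tPREP1\t87\t55\t1e-5\tR2\n")
        (rec,) = parse_plink_table(f)
        assert rec.evalue == 1e-5 and rec.replicate == "R2"

    def test_loop_row_empty_peptide_b(self, tmp_path):
        f = tmp_path / "ids.tsv"
        f.write_text(self.HEADER + "IKEKTVLSIR\t2\tPBX1\t\t4\t\t85\t87\t\t\n")
        (rec,) = parse_plink_table(f)
        assert rec.is_loop and rec.protein_b == "PBX1"

    def test_empty_file(self, tmp_path):
        f = tmp_path / "ids.tsv"
        f.write_text("")
        assert parse_plink_table(f) == []

    def test_bad_row_reports_line_number(self, tmp_path):
        f = tmp_path / "ids.tsv"
        f.write_text(self.HEADER +
                     "KTVLSIR\t1\tPBX1\tSQTPMDVDKQAIYR\t9\tPREP1\t87\t55\t1e-5\tR1\n"
                     "KTVLSIR\tbad\tPBX1\tSQTPMDVDKQAIYR\t9\tPREP1\t87\t55\t\t\n")
        with pytest.raises(ValueError, match=":3"):
            parse_plink_table(f)

    def test_missing_required_column(self, tmp_path):
        f = tmp_path / "ids.tsv"
        f.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ValueError, match="missing required column"):
            parse_plink_table(f)


def good_ions(**kw):
    defaults = dict(matched_y_a=(2, 3, 4, 5), matched_y_b=(1, 2, 3, 4),
                    n_peaks_total=40, n_peaks_assigned=24)
    defaults.update(kw)
    return SpectrumAnnotation(**defaults)


class TestCuration:
    def test_confident_record_kept(self):
        rec = ident(evalue=5e-4, ions=good_ions())
        res = curate_identifications([rec])
        assert res.kept == [rec] and not res.rejected

    def test_evalue_threshold_is_strict(self):
        res = curate_identifications([ident(evalue=2e-3, ions=good_ions()),
                                      ident(evalue=1e-3, ions=good_ions())])
        assert [reason for _, reason in res.rejected] == ["evalue", "evalue"]

    def test_broken_ion_run_rejected(self):
        rec = ident(evalue=5e-4, ions=good_ions(matched_y_b=(1, 2, 4, 5)))
        res = curate_identifications([rec])
        assert res.rejected[0][1] == "consecutive-ions"

    def test_minority_assignment_rejected(self):
        rec = ident(evalue=5e-4, ions=good_ions(n_peaks_assigned=20))
        res = curate_identifications([rec])
        assert res.rejected[0][1] == "majority-assigned"

    def test_unannotated_needs_permissive(self):
        rec = ident()
        assert curate_identifications([rec]).rejected[0][1] == "missing-annotation"
        res = curate_identifications([rec], permissive=True)
        assert res.kept == [rec] and res.uncurated == [rec]

    def test_loop_checks_single_peptide(self):
        rec = PeptideIdentification(
            peptide_a="IKEKTVLSIR", pos_a=2, pos_b=4, peptide_b=None,
            protein_a="PBX1", protein_b="PBX1", residue_a=85, residue_b=87,
            evalue=1e-5, ions=good_ions(matched_y_b=()))
        assert curate_identifications([rec]).kept == [rec]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 12), max_size=12))
    def test_longest_run_matches_oracle(self, ordinals):
        assert longest_run(ordinals) == oracles.longest_consecutive(ordinals)


class TestMapping:
    PBX1 = ProteinRecord("PBX1", "A" * 83 + "IKEKTVLSIR" + "A" * 50)

    def test_absolute_from_peptide_offset(self):
        rec = ident(peptide_b=None, pos_b=4, pos_a=2, peptide_a="IKEKTVLSIR",
                    protein_b="PBX1", residue_a=None, residue_b=None)
        mapped = map_to_residues(rec, [self.PBX1])
        assert (mapped.residue_a, mapped.residue_b) == (85, 87)

    def test_claimed_mismatch_raises(self):
        rec = PeptideIdentification(
            peptide_a="KTVLSIR", pos_a=1, protein_a="PBX1",
            peptide_b="IKEKTVLSIR", pos_b=2, protein_b="PBX1",
            residue_a=90, residue_b=85)
        with pytest.raises(MappingError, match="disagrees"):
            map_to_residues(rec, [self.PBX1])

    def test_position_one_of_peptide_at_start(self):
        prot = ProteinRecord("P", "KTVLSIR")
        rec = PeptideIdentification(
            peptide_a="KTVLSIR", pos_a=1, protein_a="P",
            peptide_b="KTVLSIR", pos_b=1, protein_b="P")
        mapped = map_to_residues(rec, [prot])
        assert mapped.residue_a == 1

    def test_ambiguous_occurrence_resolved_by_claim(self):
        prot = ProteinRecord("P", "AAKTVAAKTVA")
        rec = PeptideIdentification(
            peptide_a="AKTV", pos_a=2, protein_a="P",
            peptide_b="AKTV", pos_b=2, protein_b="P",
            residue_a=3, residue_b=8)
        mapped = map_to_residues(rec, [prot])
        assert (mapped.residue_a, mapped.residue_b) == (3, 8)
        bare = PeptideIdentification(
            peptide_a="AKTV", pos_a=2, protein_a="P",
            peptide_b="AKTV", pos_b=2, protein_b="P")
        with pytest.raises(MappingError, match="offsets"):
            map_to_residues(bare, [prot])

    def test_peptide_not_found(self):
        rec = ident(peptide_a="ANIYAAK", pos_a=7, residue_a=308)
        with pytest.raises(MappingError, match="not found"):
            map_to_residues(rec, [self.PBX1])

    def test_claimed_mode_without_sequences(self):
        mapped = map_to_residues(ident())
        assert (mapped.residue_a, mapped.residue_b) == (87, 55)


class TestOffsetAudit:
    def test_loop_positions_consistent(self):
        rec = PeptideIdentification(
            peptide_a="IKEKTVLSIR", pos_a=2, pos_b=4, peptide_b=None,
            protein_a="PBX1", protein_b="PBX1", residue_a=85, residue_b=87)
        audit = infer_peptide_offsets([rec])
        assert audit.offsets[("PBX1", "IKEKTVLSIR")] == 84
        assert not audit.contradictions

    def test_overlapping_peptides_have_independent_offsets(self):
        recs = [
            ident(),  # KTVLSIR at 87
            PeptideIdentification(
                peptide_a="IKEKTVLSIR", pos_a=2, pos_b=4, peptide_b=None,
                protein_a="PBX1", protein_b="PBX1", residue_a=85, residue_b=87),
        ]
        audit = infer_peptide_offsets(recs)
        assert audit.offsets[("PBX1", "KTVLSIR")] == 87
        assert audit.offsets[("PBX1", "IKEKTVLSIR")] == 84
        assert not audit.contradictions

    def test_contradiction_flagged(self):
        recs = [ident(), ident(residue_a=90)]
        audit = infer_peptide_offsets(recs)
        assert audit.contradictions == [("PBX1", "KTVLSIR", [87, 90])]


class TestClassifyCollapse:
    def test_classes(self):
        assert classify_link(ident()) == "inter"
        intra = ident(protein_b="PBX1", peptide_b="IKEKTVLSIR", pos_b=2,
                      residue_b=85)
        assert classify_link(intra) == "intra"
        loop = PeptideIdentification(
            peptide_a="IKEKTVLSIR", pos_a=2, pos_b=4, peptide_b=None,
            protein_a="PREP1", protein_b="PREP1", residue_a=260, residue_b=262)
        assert classify_link(loop) == "loop"

    def test_duplicate_spectra_collapse(self):
        links = collapse_redundant([ident(evalue=1e-5, replicate="R1"),
                                    ident(evalue=1e-6, replicate="R2")])
        assert len(links) == 1
        assert len(links[0].evidence) == 2
        assert links[0].best_evalue == 1e-6

    def test_symmetric_duplicate_collapses(self):
        a = ident()
        b = PeptideIdentification(
            peptide_a="SQTPMDVDKQAIYR", pos_a=9, protein_a="PREP1",
            peptide_b="KTVLSIR", pos_b=1, protein_b="PBX1",
            residue_a=55, residue_b=87)
        links = collapse_redundant([a, b])
        assert len(links) == 1

    def test_collapse_idempotent(self, xlink_truth, digest_spec):
        from talemap.synthetic import synth_xlink_dataset
        records = [map_to_residues(r) for r in
                   synth_xlink_dataset(xlink_truth, digest_spec, seed=3)]
        once = collapse_redundant(records)
        again = collapse_redundant([ev for l in once for ev in l.evidence])
        assert {l.key for l in once} == {l.key for l in again}

    def test_partition_property(self, xlink_truth, digest_spec):
        from talemap.synthetic import synth_xlink_dataset
        records = [map_to_residues(r) for r in
                   synth_xlink_dataset(xlink_truth, digest_spec, seed=5)]
        links = collapse_redundant(records)
        by_class = {"inter": 0, "intra": 0, "loop": 0}
        for l in links:
            by_class[l.link_class] += 1
        assert sum(by_class.values()) == len(links)


class TestReplicates:
    def test_both_replicates_flag(self):
        links = collapse_redundant([ident(replicate="R1"), ident(replicate="R2")])
        (link,) = aggregate_replicates(links)
        assert link.both_replicates

    def test_single_replicate_thin(self):
        (link,) = aggregate_replicates(collapse_redundant([ident(replicate="R1")]))
        assert not link.both_replicates

    def test_merging_single_replicate_evidence_sets_flag(self):
        # set-union oracle: {R1} u {R2} has size 2 -> bold
        l1 = collapse_redundant([ident(replicate="R1")])[0]
        l2 = collapse_redundant([ident(replicate="R2")])[0]
        merged = collapse_redundant(l1.evidence + l2.evidence)
        (link,) = aggregate_replicates(merged)
        assert link.replicate_support == frozenset({"R1"}) | frozenset({"R2"})
        assert link.both_replicates

    def test_monotone_under_added_evidence(self):
        base = collapse_redundant([ident(replicate="R1"), ident(replicate="R2")])
        more = collapse_redundant(base[0].evidence + [ident(replicate="R1")])
        assert aggregate_replicates(more)[0].both_replicates
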