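"""V(D)J assignment, SHM counting, CDR3 extraction, functionality,
isotype and cloning recommendations, each checked against an independent
oracle (known edit scripts, codon-table translation, substring scans)."""

import random

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from igkit.annotate import (
    annotate_read,
    annotate_record,
    assign_segments,
    call_isotype,
    count_shm,
    extract_cdr3,
    recommend_cloning,
    scan_restriction_sites,
)
from igkit.align import make_aligner
from igkit.model import (
    AnnotationError,
    AntibodyRecord,
    GermlineGene,
    GermlineReference,
    SangerRead,
)
from igkit.reference import BUILTIN_ENZYMES
from igkit.fixtures import CYS_OFFSET, make_rearrangement


def _clean_read(fixture_set, locus="heavy", insert="GACTAC"):
    v = fixture_set.db.genes(locus=locus, segment="V")[0]
    j = fixture_set.db.genes(locus=locus, segment="J")[0]
    return SangerRead("r", v.sequence + insert + j.sequence), v, j


class TestAssignSegments:
    def test_exact_rearrangement_recovers_genes_at_identity_one(self, fixture_set):
        read, v, j = _clean_read(fixture_set)
        segs = assign_segments(read, fixture_set.db)
        assert segs.v.gene.name == v.name and segs.v.identity == 1.0
        assert segs.j.gene.name == j.name and segs.j.identity == 1.0
        assert segs.locus == "heavy"

    def test_three_substitutions_counted_as_mismatches(self, fixture_set):
        read, v, j = _clean_read(fixture_set)
        seq = list(read.nucleotides)
        for pos in (30, 90, 150):
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        segs = assign_segments(SangerRead("r", "".join(seq)), fixture_set.db)
        assert segs.v.gene.name == v.name
        assert segs.v.mismatches == 3

    def test_random_read_has_no_v_gene(self, fixture_set):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        # oracle: no fixture V reaches the score floor by direct alignment
        aligner = make_aligner("local")
        scores = [aligner.score(seq, g.sequence) for g in fixture_set.db.genes(segment="V")]
        assert max(scores) < 50
        with pytest.raises(AnnotationError, match="no V gene"):
            assign_segments(SangerRead("r", seq), fixture_set.db)

    def test_embedded_d_fragment_is_reported(self, fixture_set):
        read, truth = make_rearrangement(fixture_set, "heavy", 0, seed=5, embed_d=True)
        segs = assign_segments(read, fixture_set.db)
        assert segs.d is not None
        assert segs.d.gene.name == truth.true_d
        assert segs.d.read_end - segs.d.read_start >= 5

    def test_light_chains_report_no_d(self, fixture_set):
        read, _, _ = _clean_read(fixture_set, locus="kappa")
        segs = assign_segments(read, fixture_set.db)
        assert segs.d is None and segs.locus == "kappa"


class TestCountShm:
    def test_exact_germline_counts_zero(self, fixture_set):
        read, _, _ = _clean_read(fixture_set)
        segs = assign_segments(read, fixture_set.db)
        assert count_shm(segs.v, read) == 0

    def test_planted_substitutions_counted_exactly(self, fixture_set):
        read, truth = make_rearrangement(fixture_set, "heavy", 4, seed=11)
        segs = assign_segments(read, fixture_set.db)
        assert count_shm(segs.v, read) == truth.planted_shm == 4

    def test_gap_event_counts_once(self, fixture_set):
        # 2 substitutions + one 3-nt deletion = 3 SHM (one per event)
        read, truth = make_rearrangement(fixture_set, "kappa", 2, seed=12)
        seq = read.nucleotides[:100] + read.nucleotides[103:]
        segs = assign_segments(SangerRead("r", seq), fixture_set.db)
        assert count_shm(segs.v, SangerRead("r", seq)) == 3

    def test_n_bases_excluded_from_count(self, fixture_set):
        read, _, _ = _clean_read(fixture_set)
        seq = read.nucleotides[:50] + "N" + read.nucleotides[51:]
        segs = assign_segments(SangerRead("r", seq), fixture_set.db)
        assert count_shm(segs.v, SangerRead("r", seq)) == 0


def _mini_db():
    """Tiny custom germline whose junction content is fully controlled."""
    rng = random.Random(3)
    codons = [c for c in map("".join, __import__("itertools").product("ACGT", repeat=3))
              if Seq(c).translate() != "*"]
    v_body = "".join(rng.choice(codons) for _ in range(19))
    v = GermlineGene("IGHV1-M", "heavy", "V", v_body + "TGT",
                     reading_frame_offset=0, cys104_offset=57)
    j_tail = "".join(rng.choice(codons) for _ in range(10))
    j = GermlineGene("IGHJ1-M", "heavy", "J", "TGG" + j_tail,
                     reading_frame_offset=0, anchor_offset=0)
    return GermlineReference([v, j]), v, j


class TestExtractCdr3:
    def test_known_junction_translates_to_akd(self):
        db, v, j = _mini_db()
        read = SangerRead("r", v.sequence + "GCGAAAGAC" + j.sequence)
        segs = assign_segments(read, db)
        cdr3, length, junction, problem = extract_cdr3(read, segs)
        assert problem is None
        assert junction == "TGTGCGAAAGACTGG"
        assert str(Seq(junction).translate()) == "CAKDW"  # independent oracle
        assert (cdr3, length) == ("AKD", 3)

    def test_adjacent_anchors_give_empty_cdr3(self):
        db, v, j = _mini_db()
        read = SangerRead("r", v.sequence + j.sequence)
        segs = assign_segments(read, db)
        cdr3, length, junction, problem = extract_cdr3(read, segs)
        assert problem is None and cdr3 == "" and length == 0

    def test_internal_stop_marks_unproductive(self):
        db, v, j = _mini_db()
        read = SangerRead("r", v.sequence + "GCGTAAGAC" + j.sequence)
        ann = annotate_read(read, db)
        assert "*" in ann.cdr3_aa
        assert ann.functionality == "unproductive"
        assert ann.unproductive_reason == "stop_codon"

    def test_cdr3_matches_translation_oracle_on_generated_reads(self, fixture_set):
        for seed in range(10):
            read, truth = make_rearrangement(fixture_set, "heavy", 3, seed=seed)
            ann = annotate_read(read, fixture_set.db)
            _, _, junction, _ = extract_cdr3(read, assign_segments(read, fixture_set.db))
            assert ann.cdr3_aa == str(Seq(junction).translate())[1:-1] == truth.true_cdr3_aa


class TestFunctionality:
    def test_clean_rearrangement_is_productive(self, fixture_set):
        read, _, _ = _clean_read(fixture_set)
        assert annotate_read(read, fixture_set.db).functionality == "productive"

    def test_single_nt_insertion_in_v_is_frameshift(self, fixture_set):
        read, _, _ = _clean_read(fixture_set)
        seq = read.nucleotides[:100] + "A" + read.nucleotides[100:]
        ann = annotate_read(SangerRead("r", seq), fixture_set.db)
        assert ann.functionality == "unproductive"
        assert ann.unproductive_reason == "frameshift"

    def test_engineered_stop_in_v_framework(self, fixture_set):
        read, _, _ = _clean_read(fixture_set)
        seq = read.nucleotides[:150] + "TAG" + read.nucleotides[153:]
        ann = annotate_read(SangerRead("r", seq), fixture_set.db)
        assert ann.functionality == "unproductive"
        assert ann.unproductive_reason == "stop_codon"


class TestIsotype:
    def _heavy_read(self, fixture_set, const_nt, mutate_at=()):
        read, v, j = _clean_read(fixture_set)
        igg = next(c for c in fixture_set.constants if c.isotype_label == "IgG")
        prefix = list(igg.sequence[:const_nt])
        for pos in mutate_at:
            prefix[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[prefix[pos]]
        return SangerRead("r", read.nucleotides + "".join(prefix))

    def test_exact_constant_prefix_high_confidence(self, fixture_set):
        read = self._heavy_read(fixture_set, 60)
        segs = assign_segments(read, fixture_set.db)
        assert call_isotype(read, fixture_set.constants, segs.j) == ("IgG", "high")

    def test_two_mismatches_in_sixty_still_high(self, fixture_set):
        # identity 58/60 ~ 0.967 >= 0.9 threshold
        read = self._heavy_read(fixture_set, 60, mutate_at=(20, 40))
        segs = assign_segments(read, fixture_set.db)
        assert call_isotype(read, fixture_set.constants, segs.j) == ("IgG", "high")

    def test_short_tail_without_kmer_is_undetermined(self, fixture_set):
        read = self._heavy_read(fixture_set, 10)
        segs = assign_segments(read, fixture_set.db)
        assert call_isotype(read, fixture_set.constants, segs.j) == (None, "undetermined")

    def test_kmer_fallback_gives_low_confidence(self, fixture_set):
        # 20 nt of constant: too short for the alignment route, but carries
        # the isotype-specific 12-mer tag
        read = self._heavy_read(fixture_set, 20)
        segs = assign_segments(read, fixture_set.db)
        assert call_isotype(read, fixture_set.constants, segs.j) == ("IgG", "low")


AGEI = [BUILTIN_ENZYMES["AgeI"]]


class TestRestrictionScan:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAACCGGTAAA", [("AgeI", 2)]),
            ("AAAAAAAAAA", []),
            ("ACCGGTACCGGT", [("AgeI", 0), ("AgeI", 6)]),
        ],
    )
    def test_known_scans(self, seq, expected):
        assert scan_restriction_sites(seq, AGEI) == expected

    @settings(max_examples=100, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_equals_naive_substring_oracle(self, seq):
        enzymes = list(BUILTIN_ENZYMES.values())
        oracle = sorted(
            (e.name, i)
            for e in enzymes
            for i in range(len(seq))
            if seq[i : i + len(e.recognition_site)] == e.recognition_site
        )
        assert sorted(scan_restriction_sites(seq, enzymes)) == oracle


class TestRecommendCloning:
    def test_productive_read_with_primer_is_cloneable(self, fixture_set):
        read, v, _ = _clean_read(fixture_set)
        ann = annotate_read(read, fixture_set.db, fixture_set.constants)
        rec = recommend_cloning(ann, read, fixture_set.primers)
        assert rec.cloneable
        assert rec.primer.primer_name == f"{v.family}-fwd"
        # internal-site list must agree with a direct scan of the V..J window
        window = read.nucleotides[ann.v_alignment.read_start : ann.j_alignment.read_end]
        enzymes = [BUILTIN_ENZYMES[n] for n in rec.primer.introduced_sites]
        assert [(n, p) for n, p in rec.internal_sites] == scan_restriction_sites(window, enzymes)

    def test_engineered_internal_site_warns_but_does_not_veto(self, fixture_set):
        read, v, j = _clean_read(fixture_set)
        seq = read.nucleotides[:90] + "ACCGGT" + read.nucleotides[96:]
        read2 = SangerRead("r", seq)
        ann = annotate_read(read2, fixture_set.db, fixture_set.constants)
        rec = recommend_cloning(ann, read2, fixture_set.primers)
        assert ann.functionality == "productive" and rec.cloneable
        assert ("AgeI", 90) in rec.internal_sites
        assert "AgeI@90" in rec.notes

    def test_missing_family_blocks_cloning(self, fixture_set):
        read, _, _ = _clean_read(fixture_set)
        ann = annotate_read(read, fixture_set.db, fixture_set.constants)
        rec = recommend_cloning(ann, read, {})
        assert rec.primer is None and not rec.cloneable
        assert "no primer" in rec.notes


class TestAnnotateRecord:
    def test_qc_failure_lands_in_comment_column(self, fixture_set):
        record = AntibodyRecord(mab_id="m1")
        reads = {"heavy": SangerRead("r", "ACGT" * 10, [40] * 40)}  # 40 nt
        annotate_record(record, reads, fixture_set.db, fixture_set.constants, fixture_set.primers)
        assert "QC failed: too_short" in record.comment
        assert "heavy_v_call" not in record.metadata

    def test_clean_record_fully_populated(self, fixture_set):
        read, truth = make_rearrangement(fixture_set, "heavy", 2, seed=21, mab_id="m2")
        record = AntibodyRecord(mab_id="m2")
        annotate_record(record, {"heavy": read}, fixture_set.db, fixture_set.constants,
                        fixture_set.primers)
        assert record.metadata["heavy_v_call"] == truth.true_v
        assert record.metadata["heavy_shm"] == "2"
        assert record.metadata["heavy_isotype"] == truth.true_isotype
        assert record.metadata["heavy_functionality"] == "productive"
        assert record.metadata["heavy_cloneable"] == "yes"
        assert record.comment == ""

    def test_low_confidence_isotype_flagged_for_manual_inspection(self, fixture_set):
        read, truth = make_rearrangement(fixture_set, "heavy", 0, seed=22, mab_id="m3")
        short = SangerRead("m3", read.nucleotides[:-60], read.qualities[:-60])
        record = AntibodyRecord(mab_id="m3")
        annotate_record(record, {"heavy": short}, fixture_set.db, fixture_set.constants,
                        fixture_set.primers)
        assert "manual inspection: isotype" in record.comment

    def test_annotation_is_deterministic(self, fixture_set):
        read, _ = make_rearrangement(fixture_set, "lambda", 5, seed=23)
        first = annotate_read(read, fixture_set.db, fixture_set.constants)
        second = annotate_read(read, fixture_set.db, fixture_set.constants)
        assert first == second
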