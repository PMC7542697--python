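"""Plasmid-versus-amplicon comparison: window alignment, amino-acid impact
classification, SHM recounting and the green/red/brown verdict rules."""

import random

import pytest
from Bio.Seq import Seq

from igkit.annotate import count_shm, assign_segments
from igkit.compare import (
    align_pair,
    classify_diffs,
    compare_pair,
    compare_record,
    recommend_expression,
    recount_shm,
)
from igkit.fixtures import make_plasmid_variant, make_rearrangement
from igkit.model import AntibodyRecord, SangerRead, SequenceDiff


def _pair(fixture_set, locus="heavy", n_shm=3, seed=31):
    read, truth = make_rearrangement(fixture_set, locus, n_shm, seed=seed)
    return read, truth


def _substitute(read, pos, base, quality=None):
    seq = list(read.nucleotides)
    seq[pos] = base
    quals = list(read.qualities)
    if quality is not None:
        quals[pos] = quality
    return SangerRead(read.read_id + "_p", "".join(seq), quals)


class TestAlignPair:
    def test_identical_pair_has_no_diffs(self, fixture_set):
        amp, _ = _pair(fixture_set)
        pla = SangerRead("p", amp.nucleotides, list(amp.qualities))
        pair = align_pair(amp, pla, fixture_set.db)
        assert classify_diffs(pair) == []

    def test_single_substitution_yields_one_column(self, fixture_set):
        amp, _ = _pair(fixture_set)
        pla = _substitute(amp, 120, "A" if amp.nucleotides[120] != "A" else "C")
        pair = align_pair(amp, pla, fixture_set.db)
        diffs = classify_diffs(pair)
        assert len(diffs) == 1 and diffs[0].position == 120

    def test_unalignable_plasmid_goes_brown(self, fixture_set):
        amp, _ = _pair(fixture_set)
        rng = random.Random(1)
        junk = SangerRead("p", "".join(rng.choice("ACGT") for _ in range(300)), [40] * 300)
        report = compare_pair("m", "heavy", amp, junk, fixture_set.db)
        assert report.verdict == "brown"
        assert "unalignable" in report.notes or "unalignable" in report.verdict_reason

    def test_diff_count_symmetric_under_swap(self, fixture_set):
        amp, truth = _pair(fixture_set, seed=77)
        pla, _ = make_plasmid_variant(amp, truth, "missense", seed=78)
        d1 = classify_diffs(align_pair(amp, pla, fixture_set.db))
        d2 = classify_diffs(align_pair(pla, amp, fixture_set.db))
        assert len(d1) == len(d2) == 1


class TestClassifyDiffs:
    """Amino-acid impact per diff, against the codon-table oracle."""

    def _classified(self, fixture_set, want):
        """Plant a substitution of the wanted impact and return its diff."""
        amp, _ = _pair(fixture_set, locus="kappa", seed=41)
        rng = random.Random(41)
        # frame 0, window starts at read position 0: codon i is seq[3i:3i+3]
        for ci in rng.sample(range(10, 80), 60):
            codon = amp.nucleotides[3 * ci : 3 * ci + 3]
            aa_old = str(Seq(codon).translate())
            for off in range(3):
                for base in "ACGT":
                    if base == codon[off]:
                        continue
                    new = codon[:off] + base + codon[off + 1 :]
                    aa_new = str(Seq(new).translate())
                    impact = (
                        "nonsense" if aa_new == "*"
                        else "silent" if aa_new == aa_old
                        else "missense"
                    )
                    if impact == want:
                        pla = _substitute(amp, 3 * ci + off, base)
                        pair = align_pair(amp, pla, fixture_set.db)
                        diffs = classify_diffs(pair)
                        assert len(diffs) == 1
                        return diffs[0], aa_old, aa_new
        raise AssertionError(f"no {want} substitution found")

    @pytest.mark.parametrize("impact", ["silent", "missense", "nonsense"])
    def test_substitution_impact_matches_codon_oracle(self, fixture_set, impact):
        diff, aa_old, aa_new = self._classified(fixture_set, impact)
        assert diff.kind == impact
        assert diff.aa_amplicon == aa_old
        assert diff.aa_plasmid == aa_new

    def test_gap_column_is_indel(self, fixture_set):
        amp, truth = _pair(fixture_set, seed=42)
        pla, _ = make_plasmid_variant(amp, truth, "indel", seed=43)
        pair = align_pair(amp, pla, fixture_set.db)
        kinds = {d.kind for d in classify_diffs(pair)}
        assert kinds == {"indel"}

    def test_primer_region_and_low_quality_flags(self, fixture_set):
        amp, _ = _pair(fixture_set, seed=44)
        # diff inside the leading 25-nt primer window, at a Phred-8 base
        pla = _substitute(amp, 10, "A" if amp.nucleotides[10] != "A" else "C", quality=8)
        pair = align_pair(amp, pla, fixture_set.db)
        (diff,) = classify_diffs(pair)
        assert diff.in_primer_region and diff.low_quality


class TestRecountShm:
    def test_clean_clone_preserves_count(self, fixture_set):
        amp, truth = _pair(fixture_set, n_shm=6, seed=51)
        pla, _ = make_plasmid_variant(amp, truth, "none", seed=52)
        assert recount_shm(amp, fixture_set.db) == 6
        assert recount_shm(pla, fixture_set.db) == 6

    def test_primer_artifacts_inflate_amplicon_count_only(self, fixture_set):
        amp, truth = _pair(fixture_set, n_shm=6, seed=53)
        pla, _ = make_plasmid_variant(amp, truth, "none", seed=54)
        # a mismatching cloning primer overwrote two bases near the read start
        artifact = amp
        for pos in (10, 16):
            artifact = _substitute(artifact, pos, "A" if artifact.nucleotides[pos] != "A" else "C")
        assert recount_shm(artifact, fixture_set.db) == 8
        assert recount_shm(pla, fixture_set.db) == 6

    def test_germline_identical_pair_counts_zero(self, fixture_set):
        amp, truth = _pair(fixture_set, n_shm=0, seed=55)
        pla, _ = make_plasmid_variant(amp, truth, "none", seed=56)
        assert (recount_shm(amp, fixture_set.db), recount_shm(pla, fixture_set.db)) == (0, 0)

    def test_recount_equals_annotation_count_on_same_read(self, fixture_set):
        amp, _ = _pair(fixture_set, n_shm=4, seed=57)
        segs = assign_segments(amp, fixture_set.db)
        assert recount_shm(amp, fixture_set.db) == count_shm(segs.v, amp)


def _diff(kind, in_primer=False, low_q=False, codon=7):
    return SequenceDiff(
        position=3 * codon, amplicon_nt="A", plasmid_nt="G", codon_index=codon,
        aa_amplicon="K", aa_plasmid="E" if kind != "silent" else "K",
        kind=kind, in_primer_region=in_primer, low_quality=low_q,
    )


class TestRecommendExpression:
    def test_zero_diffs_is_green_identical(self):
        assert recommend_expression([]) == ("green", "identical")

    def test_silent_diffs_never_block_green(self):
        verdict, _ = recommend_expression([_diff("silent"), _diff("silent", codon=9)])
        assert verdict == "green"

    def test_confident_missense_is_red_with_codon(self):
        verdict, reason = recommend_expression([_diff("missense")])
        assert verdict == "red" and "codon 7" in reason

    def test_low_quality_missense_is_brown(self):
        verdict, reason = recommend_expression([_diff("missense", low_q=True)])
        assert verdict == "brown" and "manual inspection" in reason

    def test_primer_region_change_alone_is_brown(self):
        verdict, _ = recommend_expression([_diff("missense", in_primer=True)])
        assert verdict == "brown"

    def test_alignment_failure_is_brown(self):
        verdict, _ = recommend_expression([], alignment_ok=False)
        assert verdict == "brown"


class TestCompareRecord:
    @pytest.mark.parametrize("kind,expected", [("none", "green"), ("missense", "red"),
                                               ("missense_lowq", "brown")])
    def test_verdict_serialized_into_record(self, fixture_set, kind, expected):
        amp, truth = _pair(fixture_set, locus="lambda", seed=61)
        pla, truth = make_plasmid_variant(amp, truth, kind, seed=62)
        record = AntibodyRecord(mab_id=truth.mab_id)
        reports = compare_record(record, {"lambda": amp}, {"lambda": pla}, fixture_set.db)
        assert reports["lambda"].verdict == expected == truth.expected_verdict
        assert record.verdict_color == expected
        assert record.metadata["lambda_verdict"] == expected
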