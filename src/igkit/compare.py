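"""Plasmid-versus-amplicon verification before antibody expression.

A cloned expression plasmid is released for expression only when its Ig
variable region is 100% identical to the amplified cDNA at the amino-acid
level.  This module aligns the two reads over the variable region
(V start through J end, each read anchored by its own germline V
alignment), classifies every nucleotide difference by its amino-acid
impact (silent / missense / nonsense / indel), recounts somatic
hypermutation independently on both reads so primer-introduced artifacts
at the read start become visible, and issues a traffic-light verdict:

* **green** — suitable for expression: no amino-acid-changing difference
  outside the primer-binding windows and no difference at a low-quality
  base.  Silent differences never block green.
* **red** — pick another colony: at least one confidently-called
  amino-acid-changing difference outside the primer windows.
* **brown** — manual inspection: alignment failure, any difference at a
  low-quality base, or amino-acid-changing differences confined to the
  primer windows (primer artifacts cannot be auto-adjudicated).

The verdict logic is asymmetric by design: a false green costs a wasted
expression run on a wrong antibody, so anything uncertain falls to brown
rather than green.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from igkit import align as _al
from igkit.config import CompareConfig, Config
from igkit.model import (
    AnnotationError,
    AntibodyRecord,
    ComparisonReport,
    GermlineReference,
    SangerRead,
    SequenceDiff,
)
from igkit.annotate import assign_segments, count_shm

AA_CHANGING = frozenset({"missense", "nonsense", "indel"})


@dataclass
class PairAlignment:
    """Global alignment of the two variable-region windows plus bookkeeping."""

    amplicon: SangerRead
    plasmid: SangerRead
    amp_window: tuple[int, int]  # V start .. J end in amplicon coordinates
    pla_window: tuple[int, int]
    frame_offset: int  # offset of the first full codon within the window
    alignment: object = None
    notes: list[str] = field(default_factory=list)


def align_pair(
    amplicon: SangerRead,
    plasmid: SangerRead,
    db: GermlineReference,
    config: Config | None = None,
) -> PairAlignment:
    """Anchor both reads on their own germline V/J and globally align the windows.

    Raises AnnotationError("plasmid unalignable") when the plasmid has no
    germline V above the score floor — the caller turns that into a brown
    verdict.
    """
    config = config or Config()
    amp_segs = assign_segments(amplicon, db, config.align)
    try:
        pla_segs = assign_segments(plasmid, db, config.align)
    except AnnotationError as exc:
        raise AnnotationError("plasmid unalignable") from exc
    amp_w = (amp_segs.v.read_start, amp_segs.j.read_end)
    pla_w = (pla_segs.v.read_start, pla_segs.j.read_end)
    win_a = amplicon.nucleotides[amp_w[0] : amp_w[1]]
    win_p = plasmid.nucleotides[pla_w[0] : pla_w[1]]
    aligner = _al.make_aligner(
        "global",
        config.align.match,
        config.align.mismatch,
        config.align.gap_open,
        config.align.gap_extend,
    )
    aln = _al.align_pairwise(aligner, win_a, win_p)
    v = amp_segs.v
    frame_offset = (v.gene.reading_frame_offset - v.gene_start) % 3
    pair = PairAlignment(
        amplicon=amplicon,
        plasmid=plasmid,
        amp_window=amp_w,
        pla_window=pla_w,
        frame_offset=frame_offset,
        alignment=aln,
    )
    if amplicon.qualities is None or plasmid.qualities is None:
        pair.notes.append("no quality data")
    return pair


def _codon_window(seq: str, frame_offset: int, codon_index: int) -> str:
    start = frame_offset + 3 * codon_index
    return seq[start : start + 3]


def classify_diffs(pair: PairAlignment, config: CompareConfig | None = None) -> list[SequenceDiff]:
    """Turn every mismatch/gap column of the pair alignment into a SequenceDiff.

    Codon impact is computed under the amplicon's V reading frame: the
    amplicon codon containing the column is re-translated with the
    aligned plasmid bases substituted in.  Gap columns are classed
    ``indel`` (no amino acids reported).  Differences within the
    primer-binding windows (first/last ``primer_region_nt`` of the
    compared window) or at bases below the quality threshold on either
    read are flagged, which downgrades their evidential weight in the
    verdict.
    """
    cfg = config or CompareConfig()
    win_a = pair.amplicon.nucleotides[pair.amp_window[0] : pair.amp_window[1]]
    win_p = pair.plasmid.nucleotides[pair.pla_window[0] : pair.pla_window[1]]
    cols = list(_al.iter_columns(pair.alignment))

    # Plasmid base per amplicon-window position (for codon re-translation).
    sub: dict[int, str] = {}
    for a, p in cols:
        if a is not None and p is not None:
            sub[a] = win_p[p]

    qual_a = pair.amplicon.qualities
    qual_p = pair.plasmid.qualities
    win_len = len(win_a)
    diffs: list[SequenceDiff] = []
    for a, p in cols:
        base_a = win_a[a] if a is not None else "-"
        base_p = win_p[p] if p is not None else "-"
        if a is not None and p is not None and base_a == base_p:
            continue
        pos = a if a is not None else min(sub.keys() | {win_len - 1}, default=0)
        if a is None:
            # Insertion in the plasmid: anchor at the nearest preceding
            # amplicon column for position/primer bookkeeping.
            prev = [c[0] for c in cols if c[0] is not None and c[1] is not None and c[1] < p]
            pos = prev[-1] if prev else 0
        codon_index = max(0, (pos - pair.frame_offset) // 3)
        if a is None or p is None:
            kind = "indel"
            aa_a = aa_p = None
        else:
            codon_a = _codon_window(win_a, pair.frame_offset, codon_index)
            codon_start = pair.frame_offset + 3 * codon_index
            codon_p = "".join(
                sub.get(codon_start + k, codon_a[k] if k < len(codon_a) else "")
                for k in range(3)
            )
            if len(codon_a) < 3 or len(codon_p) < 3:
                aa_a = aa_p = None
                kind = "indel"  # truncated terminal codon: treat as structural
            else:
                aa_a = _al.translate_codon(codon_a)
                aa_p = _al.translate_codon(codon_p)
                if aa_p == "*":
                    kind = "nonsense"
                elif aa_a == aa_p:
                    kind = "silent"
                else:
                    kind = "missense"
        in_primer = pos < cfg.primer_region_nt or pos >= win_len - cfg.primer_region_nt
        low_q = False
        if a is not None and qual_a is not None:
            low_q = low_q or qual_a[pair.amp_window[0] + a] < cfg.low_quality_phred
        if p is not None and qual_p is not None:
            low_q = low_q or qual_p[pair.pla_window[0] + p] < cfg.low_quality_phred
        diffs.append(
            SequenceDiff(
                position=pos,
                amplicon_nt=base_a,
                plasmid_nt=base_p,
                codon_index=codon_index,
                aa_amplicon=aa_a,
                aa_plasmid=aa_p,
                kind=kind,
                in_primer_region=in_primer,
                low_quality=low_q,
            )
        )
    return diffs


def recount_shm(read: SangerRead, db: GermlineReference, config: Config | None = None) -> int:
    """SHM count of one read against its best germline V.

    Shares the counting implementation with the annotation stage so the
    amplicon/plasmid pair is counted by the identical algorithm; diverging
    counts expose primer-introduced artifacts at the amplicon read start.
    """
    config = config or Config()
    segs = assign_segments(read, db, config.align)
    return count_shm(segs.v, read)


def recommend_expression(
    diffs: list[SequenceDiff], alignment_ok: bool = True
) -> tuple[str, str]:
    """Traffic-light verdict from the classified differences.  Total function."""
    if not alignment_ok:
        return "brown", "plasmid unalignable — manual inspection"
    confident_changing = [
        d for d in diffs
        if d.kind in AA_CHANGING and not d.in_primer_region and not d.low_quality
    ]
    if confident_changing:
        d = confident_changing[0]
        if d.kind == "indel":
            return "red", f"indel at window position {d.position}"
        return "red", f"aa change at codon {d.codon_index}"
    low_quality = [d for d in diffs if d.low_quality]
    if low_quality:
        return "brown", "low-quality difference — manual inspection"
    primer_changing = [d for d in diffs if d.kind in AA_CHANGING and d.in_primer_region]
    if primer_changing:
        return "brown", "aa-changing difference in primer region — manual inspection"
    if not diffs:
        return "green", "identical"
    return "green", "silent differences only"


def compare_pair(
    mab_id: str,
    chain: str,
    amplicon: SangerRead,
    plasmid: SangerRead,
    db: GermlineReference,
    config: Config | None = None,
) -> ComparisonReport:
    """Full verification of one amplicon/plasmid pair."""
    config = config or Config()
    report = ComparisonReport(mab_id=mab_id, chain=chain)
    try:
        pair = align_pair(amplicon, plasmid, db, config)
    except AnnotationError as exc:
        report.verdict, report.verdict_reason = recommend_expression([], alignment_ok=False)
        report.notes = str(exc)
        return report
    report.diffs = classify_diffs(pair, config.compare)
    report.shm_amplicon = recount_shm(amplicon, db, config)
    try:
        report.shm_plasmid = recount_shm(plasmid, db, config)
    except AnnotationError:
        report.shm_plasmid = None
    report.verdict, report.verdict_reason = recommend_expression(report.diffs)
    if pair.notes:
        report.notes = "; ".join(pair.notes)
    return report


def format_diff_report(report: ComparisonReport) -> str:
    """Plain-text per-pair difference report (one line per diff)."""
    lines = [
        f"# {report.mab_id} {report.chain}: verdict={report.verdict} ({report.verdict_reason})",
        f"# SHM amplicon={report.shm_amplicon} plasmid={report.shm_plasmid}",
    ]
    if report.notes:
        lines.append(f"# note: {report.notes}")
    header = "position\tamplicon\tplasmid\tcodon\taa_change\tkind\tflags"
    lines.append(header)
    for d in report.diffs:
        aa = f"{d.aa_amplicon or '-'}>{d.aa_plasmid or '-'}"
        flags = ",".join(
            name
            for name, on in (("primer_region", d.in_primer_region), ("low_quality", d.low_quality))
            if on
        )
        lines.append(
            f"{d.position}\t{d.amplicon_nt}\t{d.plasmid_nt}\t{d.codon_index}\t{aa}\t{d.kind}\t{flags}"
        )
    return "\n".join(lines) + "\n"


def compare_record(
    record: AntibodyRecord,
    amplicon_reads: dict[str, SangerRead],
    plasmid_reads: dict[str, SangerRead],
    db: GermlineReference,
    config: Config | None = None,
) -> dict[str, ComparisonReport]:
    """Verify every chain of one record; serialize verdicts into the record.

    The worst chain verdict colors the record (red > brown > green), so a
    single bad chain is never masked by a good one.
    """
    config = config or Config()
    reports: dict[str, ComparisonReport] = {}
    comments: list[str] = []
    for chain in ("heavy", "kappa", "lambda"):
        amp = amplicon_reads.get(chain)
        pla = plasmid_reads.get(chain)
        if amp is None or pla is None:
            continue
        rep = compare_pair(record.mab_id, chain, amp, pla, db, config)
        reports[chain] = rep
        record.metadata[f"{chain}_verdict"] = rep.verdict
        record.metadata[f"{chain}_verdict_reason"] = rep.verdict_reason
        record.metadata[f"{chain}_shm_amplicon"] = (
            "" if rep.shm_amplicon is None else str(rep.shm_amplicon)
        )
        record.metadata[f"{chain}_shm_plasmid"] = (
            "" if rep.shm_plasmid is None else str(rep.shm_plasmid)
        )
        record.metadata[f"{chain}_n_diffs"] = str(len(rep.diffs))
        if rep.verdict != "green":
            comments.append(f"{chain}: {rep.verdict_reason}")
    if reports:
        severity = {"red": 2, "brown": 1, "green": 0}
        worst = max(reports.values(), key=lambda r: severity[r.verdict])
        record.verdict_color = worst.verdict
        record.metadata["verdict"] = worst.verdict
    if comments:
        record.comment = "; ".join(comments)
        record.metadata["comment"] = record.comment
    return reports
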