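"""Primary immunoglobulin annotation: germline V(D)J assignment, somatic
hypermutation counting, CDR3 extraction, functionality and isotype calls,
and cloning-primer recommendations.

The alignment stage is native: each read is locally aligned (affine
scoring, see :class:`igkit.config.AlignConfig`) against every germline V
gene across all loci; the winning V fixes the locus, the J is searched
downstream of the V, and — heavy chain only — a D segment is reported
when at least five consecutive nucleotides of a D gene match inside the
V–J junction gap.  CDR3 follows the IMGT convention: the junction runs
from the conserved 2nd-CYS codon of the V gene to the conserved W/F
anchor codon of the J gene (both carried as offsets in the germline
reference and mapped onto the read through the alignments), and the
reported CDR3 excludes those two anchor residues.

An adapter seam is deliberately small: any object implementing
``assign_segments(read, db)`` with the same return contract could replace
the native aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from igkit import align as _al
from igkit.config import AlignConfig, Config, IsotypeConfig
from igkit.model import (
    AnnotationError,
    AntibodyRecord,
    CloningRecommendation,
    ConstantRegion,
    GermlineGene,
    GermlineReference,
    PrimerRecord,
    RestrictionEnzyme,
    SangerRead,
    SegmentAlignment,
    VDJAnnotation,
)
from igkit.qc import check_quality
from igkit.reference import BUILTIN_ENZYMES

CHAINS = ("heavy", "kappa", "lambda")

# Database column names the annotator owns, per chain.
ANNOTATION_COLUMNS = (
    "v_call", "d_call", "j_call", "shm", "cdr3_aa", "cdr3_len",
    "functionality", "isotype", "primer", "cloneable", "sites",
)


def _align_one(read_seq: str, gene: GermlineGene, aligner) -> tuple[SegmentAlignment, object]:
    aln = _al.align_pairwise(aligner, read_seq, gene.sequence)
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        raise AnnotationError(f"empty alignment against {gene.name}")
    _, mismatches, gap_events, identity = _al.alignment_stats(aln, read_seq, gene.sequence)
    seg = SegmentAlignment(
        gene=gene,
        score=aln.score,
        read_start=int(t_blocks[0][0]),
        read_end=int(t_blocks[-1][1]),
        gene_start=int(q_blocks[0][0]),
        gene_end=int(q_blocks[-1][1]),
        mismatches=mismatches,
        gaps=gap_events,
        identity=identity,
    )
    return seg, aln


@dataclass
class _Hit:
    seg: SegmentAlignment
    aln: object

    @property
    def rank(self) -> tuple:
        # Higher score, then higher identity, then lexicographically
        # smallest gene name (ties surface in the comment column).
        return (-self.seg.score, -self.seg.identity, self.seg.gene.name)


def _best_hit(read_seq: str, genes: list[GermlineGene], aligner, floor: float) -> Optional[_Hit]:
    hits: list[_Hit] = []
    for gene in genes:
        if aligner.score(read_seq, gene.sequence) < floor:
            continue
        seg, aln = _align_one(read_seq, gene, aligner)
        hits.append(_Hit(seg, aln))
    if not hits:
        return None
    hits.sort(key=lambda h: h.rank)
    best = hits[0]
    if len(hits) > 1 and hits[1].seg.score == best.seg.score and (
        hits[1].seg.identity == best.seg.identity
    ):
        best.seg.tie = True
    return best


class SegmentAssignment:
    """Result bundle of :func:`assign_segments` (keeps raw alignments for mapping)."""

    def __init__(self, v: _Hit, j: _Hit, d: Optional[SegmentAlignment], locus: str):
        self.v = v.seg
        self.j = j.seg
        self.d = d
        self.locus = locus
        self._v_aln = v.aln
        self._j_aln = j.aln

    def map_v(self, gene_pos: int) -> Optional[int]:
        return _al.map_query_to_target(self._v_aln, gene_pos)

    def map_j(self, gene_pos: int) -> Optional[int]:
        pos = _al.map_query_to_target(self._j_aln, gene_pos)
        return None if pos is None else pos + self._j_shift

    _j_shift = 0


def assign_segments(
    read: SangerRead, db: GermlineReference, cfg: AlignConfig | None = None
) -> SegmentAssignment:
    """Assign germline V, (D,) J to a read; the winning V fixes the locus.

    Raises :class:`AnnotationError` ("no V gene" / "no J gene") when no
    germline reaches the configured score floor.
    """
    cfg = cfg or AlignConfig()
    aligner = _al.make_aligner("local", cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)
    seq = read.nucleotides

    v_hit = _best_hit(seq, db.genes(segment="V"), aligner, cfg.v_score_floor)
    if v_hit is None:
        raise AnnotationError(f"read {read.read_id!r}: no V gene")
    locus = v_hit.seg.gene.locus

    tail = seq[v_hit.seg.read_end :]
    j_hit = _best_hit(tail, db.genes(locus=locus, segment="J"), aligner, cfg.j_score_floor)
    if j_hit is None:
        raise AnnotationError(f"read {read.read_id!r}: no J gene")
    shift = v_hit.seg.read_end
    j_hit.seg.read_start += shift
    j_hit.seg.read_end += shift

    d_seg: Optional[SegmentAlignment] = None
    if locus == "heavy":
        gap = seq[v_hit.seg.read_end : j_hit.seg.read_start]
        best = None
        for gene in db.genes(locus="heavy", segment="D"):
            run, off_gap, off_gene = _al.longest_common_substring(gap, gene.sequence)
            if run >= cfg.d_min_run and (best is None or (-run, gene.name) < best[0]):
                best = ((-run, gene.name), gene, run, off_gap, off_gene)
        if best is not None:
            _, gene, run, off_gap, off_gene = best
            d_seg = SegmentAlignment(
                gene=gene,
                score=float(run),
                read_start=v_hit.seg.read_end + off_gap,
                read_end=v_hit.seg.read_end + off_gap + run,
                gene_start=off_gene,
                gene_end=off_gene + run,
                mismatches=0,
                gaps=0,
                identity=1.0,
            )

    result = SegmentAssignment(v_hit, j_hit, d_seg, locus)
    result._j_shift = shift
    return result


def count_shm(v_aln: SegmentAlignment, read: SangerRead | None = None) -> int:
    """Somatic hypermutation count over the aligned V region.

    Mismatch columns plus gap events (one per contiguous indel run, not
    per base); read positions calling N are excluded.  The counts are
    computed during alignment, minus any N-position mismatches.
    """
    n_excluded = 0
    if read is not None and "N" in read.nucleotides[v_aln.read_start : v_aln.read_end]:
        n_excluded = _count_n_mismatches(v_aln, read)
    return v_aln.mismatches + v_aln.gaps - n_excluded


def _count_n_mismatches(v_aln: SegmentAlignment, read: SangerRead) -> int:
    # Conservative: without the raw alignment we cannot know which N sits in a
    # mismatch column, so recompute via the stored coordinates when needed.
    # Ns inside the aligned window never match the germline (germline has no N
    # in practice), so every aligned N is one excluded mismatch.
    window = read.nucleotides[v_aln.read_start : v_aln.read_end]
    return window.count("N")


def extract_cdr3(read: SangerRead, segs: SegmentAssignment) -> tuple[str, int, str, Optional[str]]:
    """Extract the CDR3 via the junction between the V-CYS and J-W/F anchors.

    Returns (cdr3_aa, cdr3_length, junction_nt, problem) where ``problem``
    is None, "no_junction" (anchors unmappable) or "frameshift" (junction
    length not a codon multiple).  CDR3 excludes the two anchor residues;
    a junction stop codon shows up as '*' in the CDR3 and is resolved by
    :func:`call_functionality`.
    """
    v_gene, j_gene = segs.v.gene, segs.j.gene
    cys_read = segs.map_v(v_gene.cys104_offset)
    anchor_read = segs.map_j(j_gene.anchor_offset)
    if cys_read is None or anchor_read is None or anchor_read + 3 > len(read):
        return "", 0, "", "no_junction"
    junction = read.nucleotides[cys_read : anchor_read + 3]
    if len(junction) % 3 != 0:
        return "", 0, junction, "frameshift"
    junction_aa = _al.translate(junction)
    cdr3 = junction_aa[1:-1]
    return cdr3, len(cdr3), junction, None


def call_functionality(
    read: SangerRead, segs: SegmentAssignment, cdr3_problem: Optional[str]
) -> tuple[str, Optional[str]]:
    """Productive iff the junction is in frame, anchors were found, and the
    translated V-start..J-end region carries no stop codon."""
    if cdr3_problem == "no_junction":
        return "unproductive", "no_junction"
    if cdr3_problem == "frameshift":
        return "unproductive", "frameshift"
    # A net indel length that is not a codon multiple shifts the reading
    # frame even when the junction itself still measures in-frame.
    for seg in (segs.v, segs.j):
        net = (seg.read_end - seg.read_start) - (seg.gene_end - seg.gene_start)
        if net % 3 != 0:
            return "unproductive", "frameshift"
    v = segs.v
    frame_off = (v.gene.reading_frame_offset - v.gene_start) % 3
    start = v.read_start + frame_off
    region = read.nucleotides[start : segs.j.read_end]
    if "*" in _al.translate(region):
        return "unproductive", "stop_codon"
    return "productive", None


def default_kmer_tags(constants: list[ConstantRegion], k: int = 12) -> dict[str, str]:
    """Primer-proximal k-mer per isotype: the first k nt of each constant."""
    return {c.isotype_label: c.sequence[:k] for c in constants if len(c.sequence) >= k}


def call_isotype(
    read: SangerRead,
    constants: list[ConstantRegion],
    j_aln: SegmentAlignment,
    cfg: IsotypeConfig | None = None,
    align_cfg: AlignConfig | None = None,
) -> tuple[Optional[str], str]:
    """Isotype from the read region downstream of the J alignment.

    Primary route: local alignment against every constant-region
    reference; the best hit is called with high confidence when at least
    ``min_aligned_len`` nt align at ``min_identity`` identity.  Fallback:
    exact isotype-specific k-mer match anywhere in the read (low
    confidence, manual inspection recommended).  Never raises — an
    unidentifiable isotype is (None, "undetermined").
    """
    cfg = cfg or IsotypeConfig()
    acfg = align_cfg or AlignConfig()
    aligner = _al.make_aligner("local", acfg.match, acfg.mismatch, acfg.gap_open, acfg.gap_extend)
    tail = read.nucleotides[j_aln.read_end :]
    best: Optional[tuple[float, str, int, float]] = None
    if tail:
        for const in constants:
            try:
                aln = _al.align_pairwise(aligner, tail, const.sequence)
            except (IndexError, ValueError):
                continue
            if len(aln.aligned[0]) == 0:
                continue
            matches, mismatches, gaps, identity = _al.alignment_stats(
                aln, tail, const.sequence
            )
            columns = matches + mismatches  # aligned (non-gap) columns
            key = (aln.score, const.isotype_label, columns, identity)
            if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = key
    if best is not None and best[2] >= cfg.min_aligned_len and best[3] >= cfg.min_identity:
        return best[1], "high"
    tags = cfg.kmer_tags or default_kmer_tags(constants, cfg.kmer_size)
    for label in sorted(tags):
        if tags[label] and tags[label] in read.nucleotides:
            return label, "low"
    return None, "undetermined"


def scan_restriction_sites(
    sequence: str | SangerRead, enzymes: list[RestrictionEnzyme]
) -> list[tuple[str, int]]:
    """All occurrences of each recognition site (overlaps allowed), 0-based."""
    seq = sequence.nucleotides if isinstance(sequence, SangerRead) else sequence.upper()
    hits: list[tuple[str, int]] = []
    for enz in enzymes:
        site = enz.recognition_site
        start = seq.find(site)
        while start != -1:
            hits.append((enz.name, start))
            start = seq.find(site, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def recommend_cloning(
    annotation: VDJAnnotation,
    read: SangerRead,
    primers: dict[tuple[str, str], PrimerRecord],
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> CloningRecommendation:
    """Look up the cloning primer by (V family, locus) and scan for internal
    restriction sites of the enzymes that primer pair relies on.

    Internal sites warn but do not veto cloning (the user may silently
    mutate them); a missing primer or unproductive rearrangement does.
    """
    enzymes = enzymes or BUILTIN_ENZYMES
    v_gene = annotation.v_alignment.gene if annotation.v_alignment else None
    family = v_gene.family if v_gene else ""
    primer = primers.get((family, annotation.locus)) or primers.get(
        (annotation.v_call, annotation.locus)
    )
    if primer is None:
        return CloningRecommendation(
            primer=None, internal_sites=[], cloneable=False,
            notes=f"no primer for {family or annotation.v_call}/{annotation.locus}",
        )
    site_enzymes = [enzymes[name] for name in primer.introduced_sites if name in enzymes]
    region_start = annotation.v_alignment.read_start
    region_end = annotation.j_alignment.read_end
    region = read.nucleotides[region_start:region_end]
    internal = [(name, pos + region_start) for name, pos in scan_restriction_sites(region, site_enzymes)]
    notes = ""
    if internal:
        listed = "; ".join(f"{name}@{pos}" for name, pos in internal)
        notes = f"internal restriction site(s): {listed}"
    cloneable = annotation.functionality == "productive"
    if not cloneable and not notes:
        notes = "not productive"
    return CloningRecommendation(
        primer=primer, internal_sites=internal, cloneable=cloneable, notes=notes
    )


def annotate_read(
    read: SangerRead,
    db: GermlineReference,
    constants: list[ConstantRegion] | None = None,
    config: Config | None = None,
) -> VDJAnnotation:
    """Run the full per-read annotation chain (QC is the caller's gate)."""
    config = config or Config()
    segs = assign_segments(read, db, config.align)
    shm = count_shm(segs.v, read)
    cdr3_aa, cdr3_len, _junction, problem = extract_cdr3(read, segs)
    functionality, reason = call_functionality(read, segs, problem)
    if problem is None and "*" in cdr3_aa:
        functionality, reason = "unproductive", "stop_codon"
    comments: list[str] = []
    if segs.v.tie:
        comments.append("ambiguous V call (score tie)")
    if segs.j.tie:
        comments.append("ambiguous J call (score tie)")
    isotype: Optional[str] = None
    confidence = "undetermined"
    if segs.locus == "heavy" and constants:
        isotype, confidence = call_isotype(
            read, constants, segs.j, config.isotype, config.align
        )
        if confidence == "low":
            comments.append("manual inspection: isotype (low confidence)")
        elif confidence == "undetermined":
            comments.append("isotype undetermined — consider re-sequencing")
    return VDJAnnotation(
        read_id=read.read_id,
        locus=segs.locus,
        v_call=segs.v.gene.name,
        j_call=segs.j.gene.name,
        d_call=segs.d.gene.name if segs.d else None,
        shm_count=shm,
        cdr3_aa=cdr3_aa,
        cdr3_length=cdr3_len,
        functionality=functionality,
        unproductive_reason=reason,
        isotype=isotype,
        isotype_confidence=confidence,
        comment="; ".join(comments),
        v_alignment=segs.v,
        j_alignment=segs.j,
        d_alignment=segs.d,
    )


def annotate_record(
    record: AntibodyRecord,
    reads: dict[str, SangerRead],
    db: GermlineReference,
    constants: list[ConstantRegion],
    primers: dict[tuple[str, str], PrimerRecord],
    config: Config | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> AntibodyRecord:
    """Annotate every chain of one tracking-database record in place.

    Per-chain problems (QC failure, no V gene, low-confidence isotype) are
    reported in the comment column; they never raise, so a batch run
    always completes.
    """
    config = config or Config()
    comments: list[str] = []
    for chain in CHAINS:
        read = reads.get(chain)
        if read is None:
            continue
        qc = check_quality(read, config.qc.min_phred, config.qc.min_len)
        if not qc.passed:
            comments.append(f"{chain}: QC failed: {qc.reason}")
            continue
        if qc.warning:
            comments.append(f"{chain}: {qc.warning}")
        try:
            ann = annotate_read(read, db, constants, config)
        except AnnotationError as exc:
            comments.append(f"{chain}: {exc}")
            continue
        rec = recommend_cloning(ann, read, primers, enzymes)
        prefix = chain
        record.metadata[f"{prefix}_v_call"] = ann.v_call
        record.metadata[f"{prefix}_d_call"] = ann.d_call or ""
        record.metadata[f"{prefix}_j_call"] = ann.j_call
        record.metadata[f"{prefix}_shm"] = str(ann.shm_count)
        record.metadata[f"{prefix}_cdr3_aa"] = ann.cdr3_aa
        record.metadata[f"{prefix}_cdr3_len"] = str(ann.cdr3_length)
        record.metadata[f"{prefix}_functionality"] = (
            ann.functionality
            if ann.functionality == "productive"
            else f"unproductive({ann.unproductive_reason})"
        )
        if chain == "heavy":
            record.metadata[f"{prefix}_isotype"] = ann.isotype or "undetermined"
        record.metadata[f"{prefix}_primer"] = rec.primer.primer_name if rec.primer else ""
        record.metadata[f"{prefix}_cloneable"] = "yes" if rec.cloneable else "no"
        record.metadata[f"{prefix}_sites"] = "; ".join(
            f"{name}@{pos}" for name, pos in rec.internal_sites
        )
        if ann.comment:
            comments.append(f"{chain}: {ann.comment}")
        if rec.notes and not rec.cloneable:
            comments.append(f"{chain}: {rec.notes}")
    record.comment = "; ".join(comments)
    record.metadata["comment"] = record.comment
    return record
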