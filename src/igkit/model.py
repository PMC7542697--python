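"""Core domain types for the single-cell antibody cloning workflow.

Everything downstream (quality gating, V(D)J annotation, plasmid
verification) operates on these plain dataclasses.  They carry no
behaviour beyond invariant checks so that every module can be tested
against them in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

NUCLEOTIDES = frozenset("ACGTN")
LOCI = ("heavy", "kappa", "lambda")
SEGMENTS = ("V", "D", "J")
ISOTYPE_LABELS = ("IgM", "IgD", "IgG", "IgA", "IgE", "kappa", "lambda")
VERDICTS = ("green", "red", "brown")


class IgkitError(Exception):
    """Base class for all package errors."""


class ReferenceLoadError(IgkitError):
    """Malformed or inconsistent reference data (germline, constants, primers)."""


class AnnotationError(IgkitError):
    """A read could not be annotated (e.g. no V gene above the score floor)."""


class DatabaseError(IgkitError):
    """Schema problem in the xlsx tracking database."""


def _check_alphabet(seq: str, what: str, allow_n: bool = True) -> None:
    allowed = NUCLEOTIDES if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains non-nucleotide characters: {sorted(bad)!r}")


@dataclass
class SangerRead:
    """One Sanger sequencing read, the unit of all analysis.

    ``qualities`` is present for FASTQ input (per-base Phred scores) and
    ``None`` for FASTA input, in which case quality-dependent logic
    degrades gracefully and flags its output.
    """

    read_id: str
    nucleotides: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.nucleotides = self.nucleotides.upper()
        _check_alphabet(self.nucleotides, f"read {self.read_id!r}")
        if self.qualities is not None:
            if len(self.qualities) != len(self.nucleotides):
                raise ValueError(
                    f"read {self.read_id!r}: {len(self.qualities)} quality values "
                    f"for {len(self.nucleotides)} bases"
                )
            if any(q < 0 for q in self.qualities):
                raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class GermlineGene:
    """A germline V, D or J gene with the anchor metadata needed for CDR3 work.

    ``cys104_offset`` (V genes) and ``anchor_offset`` (J genes) are 0-based
    nucleotide offsets of the conserved 2nd-CYS codon and the J-TRP/J-PHE
    codon within the germline sequence; they let junction extraction run
    without any external numbering service.
    """

    name: str
    locus: str
    segment: str
    sequence: str
    reading_frame_offset: Optional[int] = None
    cys104_offset: Optional[int] = None
    anchor_offset: Optional[int] = None

    def __post_init__(self) -> None:
        from igkit.align import translate_codon  # local import avoids a cycle

        if self.locus not in LOCI:
            raise ReferenceLoadError(f"gene {self.name!r}: unknown locus {self.locus!r}")
        if self.segment not in SEGMENTS:
            raise ReferenceLoadError(f"gene {self.name!r}: unknown segment {self.segment!r}")
        if not self.sequence:
            raise ReferenceLoadError(f"gene {self.name!r}: empty sequence")
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence, f"gene {self.name!r}")
        if self.segment == "D" and self.locus != "heavy":
            raise ReferenceLoadError(f"gene {self.name!r}: D segment on {self.locus} locus")
        if self.segment in ("V", "J"):
            if self.reading_frame_offset is None or not 0 <= self.reading_frame_offset <= 2:
                raise ReferenceLoadError(
                    f"gene {self.name!r}: {self.segment} gene needs reading_frame_offset 0-2"
                )
        if self.segment == "V":
            off = self.cys104_offset
            if off is None or not 0 <= off < len(self.sequence) - 2:
                raise ReferenceLoadError(f"gene {self.name!r}: cys104_offset out of range")
            aa = translate_codon(self.sequence[off : off + 3])
            if aa != "C":
                raise ReferenceLoadError(
                    f"gene {self.name!r}: annotated cys codon translates to {aa!r}, not C"
                )
        if self.segment == "J":
            off = self.anchor_offset
            if off is None or not 0 <= off < len(self.sequence) - 2:
                raise ReferenceLoadError(f"gene {self.name!r}: anchor_offset out of range")
            aa = translate_codon(self.sequence[off : off + 3])
            if aa not in ("W", "F"):
                raise ReferenceLoadError(
                    f"gene {self.name!r}: annotated J anchor translates to {aa!r}, not W/F"
                )

    @property
    def family(self) -> str:
        """Gene family, i.e. the name up to the first hyphen (IGHV1-X -> IGHV1)."""
        return self.name.split("-")[0]


@dataclass
class ConstantRegion:
    """A constant-region reference sequence used for isotype calling."""

    isotype_label: str
    sequence: str

    def __post_init__(self) -> None:
        if self.isotype_label not in ISOTYPE_LABELS:
            raise ReferenceLoadError(f"unknown isotype label {self.isotype_label!r}")
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence, f"constant {self.isotype_label!r}")
        if len(self.sequence) < 30:
            raise ReferenceLoadError(
                f"constant {self.isotype_label!r}: sequence shorter than 30 nt"
            )


@dataclass
class PrimerRecord:
    """One row of the customizable cloning-primer table."""

    gene_key: str
    locus: str
    primer_name: str
    primer_sequence: str
    introduced_sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ReferenceLoadError(f"primer {self.primer_name!r}: unknown locus {self.locus!r}")
        self.primer_sequence = self.primer_sequence.upper()
        _check_alphabet(self.primer_sequence, f"primer {self.primer_name!r}")


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition_site: str

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        object.__setattr__(self, "recognition_site", site)
        if len(site) < 4:
            raise ReferenceLoadError(f"enzyme {self.name!r}: recognition site shorter than 4 nt")
        _check_alphabet(site, f"enzyme {self.name!r}", allow_n=False)


class GermlineReference:
    """Collection of germline genes grouped by (locus, segment)."""

    def __init__(self, genes: list[GermlineGene]):
        self._by_name: dict[str, GermlineGene] = {}
        self._groups: dict[tuple[str, str], list[GermlineGene]] = {}
        for g in genes:
            if g.name in self._by_name:
                raise ReferenceLoadError(f"duplicate gene name {g.name!r}")
            self._by_name[g.name] = g
            self._groups.setdefault((g.locus, g.segment), []).append(g)

    def genes(self, locus: Optional[str] = None, segment: Optional[str] = None) -> list[GermlineGene]:
        if locus is None and segment is None:
            return list(self._by_name.values())
        out = []
        for (loc, seg), group in self._groups.items():
            if (locus is None or loc == locus) and (segment is None or seg == segment):
                out.extend(group)
        return out

    def __getitem__(self, name: str) -> GermlineGene:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self._by_name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineReference):
            return NotImplemented
        return self._by_name == other._by_name

    @property
    def loci(self) -> list[str]:
        return sorted({loc for loc, _ in self._groups})


@dataclass
class QCResult:
    """Outcome of the read quality gate."""

    passed: bool
    length: int
    reason: Optional[str] = None  # low_quality | too_short | None
    mean_phred: Optional[float] = None
    warning: Optional[str] = None  # no_quality_data for FASTA input


@dataclass
class SegmentAlignment:
    """Best local alignment of a read against one germline segment.

    Coordinates are 0-based half-open; ``read_*`` index into the read,
    ``gene_*`` into the germline sequence.
    """

    gene: GermlineGene
    score: float
    read_start: int
    read_end: int
    gene_start: int
    gene_end: int
    mismatches: int
    gaps: int
    identity: float
    tie: bool = False


@dataclass
class VDJAnnotation:
    """Full per-read annotation result."""

    read_id: str
    locus: str
    v_call: str
    j_call: str
    d_call: Optional[str] = None
    shm_count: int = 0
    cdr3_aa: str = ""
    cdr3_length: int = 0
    functionality: str = "unproductive"  # productive | unproductive
    unproductive_reason: Optional[str] = None  # stop_codon | frameshift | no_junction
    isotype: Optional[str] = None
    isotype_confidence: str = "undetermined"  # high | low | undetermined
    comment: str = ""
    v_alignment: Optional[SegmentAlignment] = None
    j_alignment: Optional[SegmentAlignment] = None
    d_alignment: Optional[SegmentAlignment] = None


@dataclass
class CloningRecommendation:
    primer: Optional[PrimerRecord]
    internal_sites: list[tuple[str, int]]
    cloneable: bool
    notes: str = ""


@dataclass
class SequenceDiff:
    """One differing alignment column between amplicon and plasmid.

    ``position`` is the 0-based offset in the compared window, which is
    anchored at the start of the amplicon's V alignment so that codon
    indices are stable across reads.
    """

    position: int
    amplicon_nt: str
    plasmid_nt: str
    codon_index: int
    aa_amplicon: Optional[str]
    aa_plasmid: Optional[str]
    kind: str  # silent | missense | nonsense | indel
    in_primer_region: bool = False
    low_quality: bool = False


@dataclass
class ComparisonReport:
    """Plasmid-versus-amplicon verification result for one chain."""

    mab_id: str
    chain: str
    diffs: list[SequenceDiff] = field(default_factory=list)
    shm_amplicon: Optional[int] = None
    shm_plasmid: Optional[int] = None
    verdict: str = "brown"
    verdict_reason: str = ""
    notes: str = ""


@dataclass
class AntibodyRecord:
    """One row of the xlsx tracking database: one single cell, one mAb.

    ``metadata`` holds every user column in original order; annotation and
    verification write into well-known keys of the same mapping so the
    round-trip stays byte-for-byte lossless for columns we do not own.
    """

    mab_id: str
    metadata: dict[str, str] = field(default_factory=dict)
    comment: str = ""
    verdict_color: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mab_id:
            raise DatabaseError("empty mab_id")
        if self.verdict_color is not None and self.verdict_color not in VERDICTS:
            raise DatabaseError(f"unknown verdict color {self.verdict_color!r}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the fixture generator for one synthetic read."""

    mab_id: str
    locus: str
    true_v: str
    true_j: str
    true_d: Optional[str] = None
    planted_shm: int = 0
    shm_positions: list[int] = field(default_factory=list)
    true_cdr3_aa: str = ""
    true_isotype: Optional[str] = None
    edits: list[tuple[str, int, str, str]] = field(default_factory=list)
    expected_verdict: Optional[str] = None
    seed: Optional[int] = None
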