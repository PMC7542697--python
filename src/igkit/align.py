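"""Pairwise-alignment primitives shared by annotation and comparison.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` that expose the
pieces the workflow needs: affine-scored local/global DNA alignment,
column-wise iteration, germline-to-read coordinate mapping, and codon
translation.  Scoring defaults (match +1, mismatch -2, gap open -4, gap
extend -1) live in :mod:`igkit.config`.
"""

from __future__ import annotations

from typing import Iterator, Optional

from Bio import Align
from Bio.Data.CodonTable import standard_dna_table

# Standard-code codon table with explicit stops as '*'.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = tuple(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str:
    """Translate one codon; ambiguous or short codons give 'X'."""
    return CODON_TABLE.get(codon.upper(), "X")


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon (trailing <3 nt dropped)."""
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def make_aligner(
    mode: str = "local",
    match: float = 1,
    mismatch: float = -2,
    gap_open: float = -4,
    gap_extend: float = -1,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pairwise(aligner: Align.PairwiseAligner, target: str, query: str):
    """Best alignment of query against target (first optimal one, deterministic)."""
    alignments = aligner.align(target, query)
    return alignments[0]


def iter_columns(alignment) -> Iterator[tuple[Optional[int], Optional[int]]]:
    """Yield (target_pos, query_pos) per alignment column; ``None`` marks a gap.

    Only the aligned span is covered: soft-clipped ends of a local
    alignment are not emitted.  Between aligned blocks, target-gap columns
    are emitted before query-gap columns (deterministic order).
    """
    t_blocks, q_blocks = alignment.aligned
    prev_t_end: Optional[int] = None
    prev_q_end: Optional[int] = None
    for (t_start, t_end), (q_start, q_end) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            for t in range(prev_t_end, t_start):  # query gap (deletion in query)
                yield t, None
            for q in range(prev_q_end, q_start):  # target gap (insertion in query)
                yield None, q
        for t, q in zip(range(t_start, t_end), range(q_start, q_end)):
            yield t, q
        prev_t_end, prev_q_end = t_end, q_end


def alignment_stats(alignment, target: str, query: str) -> tuple[int, int, int, float]:
    """Return (matches, mismatches, gap_events, identity) over the aligned span.

    Gap events are counted once per contiguous run, matching how somatic
    hypermutation treats an indel as a single mutational event.  Identity
    is matches over all alignment columns (gap columns included).
    """
    matches = mismatches = gap_events = columns = 0
    in_gap = False
    for t, q in iter_columns(alignment):
        columns += 1
        if t is None or q is None:
            if not in_gap:
                gap_events += 1
            in_gap = True
            continue
        in_gap = False
        if target[t] == query[q]:
            matches += 1
        else:
            mismatches += 1
    identity = matches / columns if columns else 0.0
    return matches, mismatches, gap_events, identity


def map_query_to_target(alignment, query_pos: int) -> Optional[int]:
    """Map a query (germline) coordinate onto the target (read); None if unaligned."""
    t_blocks, q_blocks = alignment.aligned
    for (t_start, _t_end), (q_start, q_end) in zip(t_blocks, q_blocks):
        if q_start <= query_pos < q_end:
            return t_start + (query_pos - q_start)
    return None


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Length and start offsets (in a, in b) of the longest exact shared substring.

    Earliest occurrence wins on ties, making D-segment detection
    deterministic.  Quadratic DP is fine at junction scale (tens of nt).
    """
    best_len = best_a = best_b = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len = cur[j]
                    best_a = i - cur[j]
                    best_b = j - cur[j]
        prev = cur
    return best_len, best_a, best_b
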