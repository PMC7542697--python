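# Methods

## Scope and model

igkit automates two stages of single-cell mAb cloning analysis: primary
annotation of amplified-cDNA Ig Sanger reads, and verification of
expression plasmids against those amplicons. Both stages share one
alignment engine and one SHM-counting implementation, so the numbers a
user compares across stages are produced by identical code paths.

The underlying biological model is the standard V(D)J picture: a read is
a mutated copy of one germline V gene, followed by a junction insert
(containing a D fragment on the heavy chain), one germline J gene, and a
stretch of constant region that identifies the isotype. Annotation is
therefore a segmentation problem solved by local alignment, and every
downstream quantity (SHM, CDR3, frame, functionality) is derived from
the segment coordinates.

## Quality gate

Reads shorter than 50 nt or with mean Phred below 12 are excluded
(`qc.min_len`, `qc.min_phred`). The aggregate is the *mean* over all
bases: a per-base threshold would reject nearly every Sanger read at the
degraded trace ends, while the mean is the conventional whole-read gate
for Sanger data. The mean used for the decision is stored in the result
so a rejected read can be audited. Length is checked first; FASTA input
(no qualities) passes the quality criterion but is flagged
`no_quality_data` through to the comment column. No trimming happens
here — trimming would silently alter SHM counts, so uncertainty is
instead handled locally at diff positions during comparison.

## Segment assignment

Alignment uses affine-gap scoring: match +1, mismatch −2, gap open −4,
gap extend −1 (`align.*` config keys), local mode for germline search
and global mode for the plasmid/amplicon window comparison. The V gene
is chosen by maximal local score over all loci's V genes (floor 50); the
winning V fixes the locus. J is searched in the read downstream of the V
end (floor 15). On the heavy chain, a D segment is reported when a D
gene shares ≥ 5 consecutive nucleotides with the V–J gap (longest common
substring; earliest occurrence on ties). Score ties are broken by higher
identity, then lexicographically smallest gene name, and flagged in the
comment column. The score floors are calibrated to the scoring scheme:
a true V match of ~270 nt scores near 270 even with 5 % mismatches,
whereas the best local alignment of an unrelated 300-nt sequence stays
well under 50.

An IgBLAST-style external aligner could be slotted in behind the same
`assign_segments` contract; the native engine keeps the package free of
external binaries.

## SHM counting

SHM = mismatch columns + gap *events* (one per contiguous indel run)
within the aligned V region; read positions calling N are excluded.
Counting indel runs once per event, rather than per base, treats a
3-nt germline-length difference as the single mutational event it is.
The comparison stage recounts SHM on amplicon and plasmid independently
with this same function; a difference between the two counts is the
signature of primer-introduced artifacts at the amplicon read start.

## CDR3 and functionality

The germline reference dialect carries the two IMGT anchors explicitly:
the 2nd-CYS codon offset on each V gene and the J-TRP/J-PHE codon offset
on each J gene, both validated at load time (the annotated codons must
translate to C and W/F). Anchors are mapped from germline coordinates
onto the read through the alignments; the junction is the read segment
from the CYS codon start through the anchor codon end, and the CDR3 is
its translation minus the two anchor residues. A junction whose length
is not a codon multiple yields `unproductive(frameshift)`; unmappable
anchors yield `unproductive(no_junction)`. Productivity additionally
requires no stop codon in the V-start..J-end translation under the V
reading frame and no net out-of-frame indel in the V or J alignment —
the latter check makes a single-nucleotide insertion deterministically a
frameshift rather than relying on a chance downstream stop.

## Isotype

The read region downstream of the J alignment is locally aligned against
every constant-region reference; the best hit is called at **high**
confidence when ≥ 30 nt align at ≥ 0.9 identity (`isotype.*` config).
Below that, a fallback looks for an exact isotype-specific 12-mer
anywhere in the read and calls at **low** confidence with a
manual-inspection comment; otherwise the isotype is **undetermined** and
re-sequencing is suggested. The default 12-mers are the first 12 nt of
each loaded constant reference — a stand-in for the primer-proximal tags
a laboratory would configure for its own primer set
(`isotype.kmer_tags`). The 30 nt / 0.9 / k=12 values are this package's
concretization of a short-read isotype heuristic; all three are config
keys.

## Cloning recommendation

The primer table is keyed by (V-gene family, locus), family being the
gene name up to the first hyphen. Internal restriction sites are scanned
over the V..J region for exactly the enzymes the matched primer pair
relies on; occurrences warn but do not veto cloning, since users
routinely mutate such sites silently — `cloneable` is false only when no
primer exists or the rearrangement is unproductive.

## Plasmid verification

Both reads are anchored by their own germline V alignment; the compared
window spans V start through J end, globally aligned. Each differing
column becomes one record: substitutions are re-translated in the
amplicon's V frame with the plasmid bases substituted into the affected
codon (silent / missense / nonsense by codon table), gap columns are
indels. Two evidence flags demote a difference: positions inside the
primer-binding windows (first/last 25 nt of the window,
`compare.primer_region_nt`) and positions where either read's Phred is
below 20 (`compare.low_quality_phred`).

Verdict rules, in order: alignment failure → **brown**; any confident
(not low-quality) missense/nonsense/indel outside primer regions →
**red**; any low-quality difference, or amino-acid-changing differences
confined to primer regions → **brown**; otherwise **green** (identical
or silent-only). Consequences worth stating explicitly: indels are
never green regardless of length, because release is defined at 100 %
amino-acid identity and even an in-frame 3-nt indel changes the protein;
and primer-region amino-acid changes resolve to brown rather than green
or red because primer-binding artifacts cannot be auto-adjudicated from
one read pair. When either read lacks qualities the low-quality flag is
unavailable; diffs are then classified on sequence alone and the report
notes "no quality data".

## Synthetic data generator

The generator emulates the *structure* of single-cell Ig Sanger data:
germline V genes of 90 codons with a CYS codon at codon 88, J genes with
a W/F anchor at offset 9, a 9-nt junction insert (optionally seeding
6 nt of a D gene), 80 nt of constant region, and Phred 35–50 qualities
(8 inside degraded windows). V genes are random non-stop codon sequences
regenerated until all pairs sit at ≤ 0.85 global-alignment identity, so
the best germline hit is unambiguous by construction. Planted SHM
substitutions avoid the CYS codon and the outermost 6 nt of V: a
terminal mismatch is clipped by *any* optimal local alignment (it always
lowers the score), so a terminal substitution would be uncountable by
construction rather than by implementation defect. Plasmid edits are
planted strictly inside the compared window and outside the primer
margins, which is what makes the expected verdict mechanically derivable
from the edit kind.

What the generator does **not** emulate: chromatogram noise profiles,
position-dependent Sanger error rates, real IMGT allele sequences and
their much closer pairwise identities, multiple primers annealing at the
read start, or chimeric reads. Passing tests therefore demonstrate that
the algorithms are correct under their stated model — unambiguous
references, localized quality loss — not that germline calls on real
data reach any particular accuracy against closely related alleles.

## Problem sizes and numerics

The test and acceptance workloads use 200 rearrangements for annotation
recovery (substitution load up to 13 of the 264 mutable V positions,
~5 %), 100 heavy reads for isotype recovery, and 500 amplicon/plasmid
pairs cycling through all six edit plans — sizes chosen so each estimate
is measured on a comfortably large sample while a full run stays in the
tens of seconds. All randomness flows from explicit integer seeds
(`random.Random`); identical inputs give byte-identical outputs, and
alignment ties resolve deterministically (score, then identity, then
gene name; first-listed optimal alignment otherwise). xlsx cells are
written with an explicit string type so user metadata is never
reinterpreted as numbers, dates or formulas.

## Known limitations

Single-strand analysis only (reads are assumed in V→J orientation, as
Sanger exports from a sequencing primer are); no clonality or lineage
analysis across cells; no chromatogram (.ab1) parsing — base calling is
upstream; human-style locus structure (heavy/kappa/lambda) is assumed;
isotype calling depends on how much constant region the read covers and
degrades to low/undetermined, by design, rather than guessing.
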