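# igkit

A toolkit for the data-analysis half of single-cell monoclonal antibody
(mAb) cloning. When B cells — for example from patient cerebrospinal
fluid — are sorted one per well and their immunoglobulin (Ig) transcripts
amplified and Sanger-sequenced, two repetitive analysis steps dominate
the workflow, and both are automated here:

1. **Annotation** (`igkit.annotate`, CLI `abase`): each amplified-cDNA
   read is quality-gated, aligned against a germline V/D/J reference to
   call the best-matching genes, the somatic hypermutation (SHM) load is
   counted, the CDR3 junction is extracted and translated, the
   rearrangement is classified productive/unproductive, the heavy-chain
   isotype is identified from the constant region downstream of J, and a
   gene-family-specific cloning primer plus internal restriction-site
   warnings are looked up. Results land in an .xlsx tracking database —
   one row per cell, user metadata columns untouched.
2. **Plasmid verification** (`igkit.compare`, CLI `cbase`): before a
   cloned expression plasmid is released for expression, its variable
   region is compared nucleotide-by-nucleotide against the source
   amplicon. Every difference is classified by amino-acid impact
   (silent / missense / nonsense / indel), SHM is recounted on both reads
   so primer artifacts become visible, and a traffic-light verdict is
   issued: **green** (100 % amino-acid identity — express), **red**
   (confident amino-acid change — pick another colony), **brown**
   (low-quality or primer-region evidence — inspect manually). The rules
   are deliberately asymmetric: anything uncertain falls to brown, never
   to green, so a green call is designed to have a positive predictive
   value of 100 %.

A deterministic synthetic-data generator (`igkit.fixtures`, CLI
`base-fixtures`) builds germline references, rearranged reads with known
V/J/SHM/CDR3 ground truth, and plasmid variants with planted edits, so
the entire pipeline is testable offline with zero downloads.

## The core calls

For a read *r* and germline genes *g*, segments are assigned by affine
local alignment (match +1, mismatch −2, gap open −4, extend −1; score
floors 50 for V, 15 for J; D reported at ≥ 5 consecutive matches inside
the V–J gap). SHM is the number of mismatch columns plus gap *events* in
the V alignment, N positions excluded. The CDR3 follows the IMGT
convention: translate the junction from the conserved 2nd-CYS codon of V
through the J-region W/F anchor codon, then drop the two anchor
residues. A rearrangement is productive iff the junction length is a
codon multiple, no net out-of-frame indel exists in V or J, and the
translated V-start..J-end region has no stop codon.

## Worked example

```
$ python examples/annotate_reads.py
read mab001: 401 nt, mean Phred 42.2, QC pass=True
V/D/J        : IGHV6-S1 / IGHD1 / IGHJ1  (locus=heavy)
SHM count    : 4   (generator planted 4)
CDR3         : RIMHPRT (7 aa)
functionality: productive
isotype      : IgM (high confidence)
cloning      : primer=IGHV6-fwd, cloneable=True
```

The annotator recovered the planted germline genes, the exact SHM count,
the translated CDR3 loop, and the isotype, and found the V-family primer
for expression cloning.

```
$ python examples/verify_plasmid.py
edit=none           verdict=green (identical); SHM amplicon=6 plasmid=6; 0 diff(s)
edit=missense       verdict=red   (aa change at codon 49); SHM amplicon=6 plasmid=7; 1 diff(s)
edit=missense_lowq  verdict=brown (low-quality difference — manual inspection); SHM amplicon=6 plasmid=7; 1 diff(s)
```

An exact clone is released (green); a missense edit is rejected (red);
the same edit under a Phred-8 trace window is deferred to a human
(brown).

`examples/run_benchmark.py` generates a small end-to-end dataset and
runs both stages; the shell equivalents are:

```
base-fixtures --out bench --n 50 --seed 7 --mix green=0.6,red=0.3,brown=0.1
abase  --db bench/records.xlsx --seqdir bench/amplicons --germline bench/germline.fasta \
       --constants bench/constants.fasta --primers bench/primers.xlsx --out annotated.xlsx
cbase  --db bench/records.xlsx --amplicons bench/amplicons --plasmids bench/plasmids \
       --germline bench/germline.fasta --out verified.xlsx
```

## Reference-data formats

Germline FASTA headers carry the metadata that makes CDR3 extraction
self-contained: `>IGHV1-X|heavy|V|frame=0|cys=264` (0-based offsets; the
cys/anchor codons are validated at load time). Constant regions are a
plain FASTA keyed by isotype label. The cloning-primer table is .xlsx
with columns `gene_key, locus, primer_name, primer_sequence,
introduced_sites`. The bundled generator emits synthetic references in
exactly these formats; real germline sets can be dropped in using the
same dialect.
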