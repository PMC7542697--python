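"""Loading and validation of reference data.

Three reference inputs drive the workflow:

* a germline V/D/J FASTA whose headers carry locus, segment and anchor
  metadata in a pipe-delimited dialect::

      >IGHV1-X|heavy|V|frame=0|cys=264
      >IGHJ1|heavy|J|frame=0|anchor=9
      >IGHD1|heavy|D

  ``frame`` is the reading-frame offset of the gene, ``cys`` the 0-based
  nucleotide offset of the conserved 2nd-CYS codon (V genes), ``anchor``
  the offset of the conserved J-TRP/J-PHE codon (J genes).  Offsets are
  validated at load time: the cys codon must translate to C and the J
  anchor to W or F.

* a constant-region FASTA with plain isotype labels as headers (IgM, IgG,
  IgA, IgD, IgE, kappa, lambda), used for isotype calling;

* a cloning-primer table (.xlsx) with columns gene_key, locus,
  primer_name, primer_sequence and introduced_sites (semicolon-separated
  restriction-enzyme names), keyed by (gene_key, locus).
"""

from __future__ import annotations

from pathlib import Path

import openpyxl
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from igkit.model import (
    ConstantRegion,
    GermlineGene,
    GermlineReference,
    PrimerRecord,
    ReferenceLoadError,
    RestrictionEnzyme,
)

PRIMER_COLUMNS = ("gene_key", "locus", "primer_name", "primer_sequence", "introduced_sites")

#: Enzymes commonly introduced by Ig expression-cloning primer sets.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("AgeI", "ACCGGT"),
        RestrictionEnzyme("SalI", "GTCGAC"),
        RestrictionEnzyme("XhoI", "CTCGAG"),
        RestrictionEnzyme("BsiWI", "CGTACG"),
        RestrictionEnzyme("HindIII", "AAGCTT"),
        RestrictionEnzyme("NheI", "GCTAGC"),
        RestrictionEnzyme("EcoRI", "GAATTC"),
        RestrictionEnzyme("BamHI", "GGATCC"),
    )
}


def load_germline_db(path: str | Path) -> GermlineReference:
    """Load a germline V/D/J FASTA in the structured-header dialect.

    Validation is eager: anchor codons, loci, segments and duplicate names
    are checked before the collection is returned.
    """
    genes: list[GermlineGene] = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split("|")
        if len(fields) < 3:
            raise ReferenceLoadError(
                f"germline record {fields[0]!r}: header needs at least name|locus|segment"
            )
        name, locus, segment = fields[0], fields[1], fields[2]
        kwargs: dict[str, int] = {}
        for extra in fields[3:]:
            key, sep, value = extra.partition("=")
            if not sep:
                raise ReferenceLoadError(f"germline record {name!r}: bad header field {extra!r}")
            try:
                ivalue = int(value)
            except ValueError:
                raise ReferenceLoadError(
                    f"germline record {name!r}: non-integer {key}={value!r}"
                ) from None
            field_name = {"frame": "reading_frame_offset", "cys": "cys104_offset",
                          "anchor": "anchor_offset"}.get(key)
            if field_name is None:
                raise ReferenceLoadError(f"germline record {name!r}: unknown header key {key!r}")
            kwargs[field_name] = ivalue
        genes.append(
            GermlineGene(name=name, locus=locus, segment=segment,
                         sequence=str(record.seq), **kwargs)
        )
    if not genes:
        raise ReferenceLoadError(f"no germline records in {path}")
    return GermlineReference(genes)


def write_germline_db(db: GermlineReference, path: str | Path) -> None:
    """Write a germline collection back out in the same header dialect."""
    records = []
    for g in db.genes():
        parts = [g.name, g.locus, g.segment]
        if g.reading_frame_offset is not None:
            parts.append(f"frame={g.reading_frame_offset}")
        if g.cys104_offset is not None:
            parts.append(f"cys={g.cys104_offset}")
        if g.anchor_offset is not None:
            parts.append(f"anchor={g.anchor_offset}")
        header = "|".join(parts)
        records.append(SeqRecord(Seq(g.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def load_constants(path: str | Path) -> list[ConstantRegion]:
    """Load constant-region references from a plain FASTA (header = isotype label)."""
    constants: list[ConstantRegion] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        label = record.description.strip()
        if label in seen:
            raise ReferenceLoadError(f"duplicate constant-region label {label!r}")
        seen.add(label)
        constants.append(ConstantRegion(isotype_label=label, sequence=str(record.seq)))
    if not constants:
        raise ReferenceLoadError(f"no constant-region records in {path}")
    return constants


def write_constants(constants: list[ConstantRegion], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.isotype_label, description="") for c in constants
    ]
    SeqIO.write(records, str(path), "fasta")


def load_primer_table(path: str | Path) -> dict[tuple[str, str], PrimerRecord]:
    """Load the cloning-primer table, keyed by (gene_key, locus)."""
    wb = openpyxl.load_workbook(str(path), read_only=True)
    ws = wb.active
    rows = ws.iter_rows(values_only=True)
    try:
        header = [str(c) if c is not None else "" for c in next(rows)]
    except StopIteration:
        raise ReferenceLoadError(f"primer table {path} is empty") from None
    missing = [c for c in PRIMER_COLUMNS if c not in header]
    if missing:
        raise ReferenceLoadError(f"primer table missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in PRIMER_COLUMNS}
    primers: dict[tuple[str, str], PrimerRecord] = {}
    for row in rows:
        if row is None or all(c is None for c in row):
            continue

        def cell(col: str) -> str:
            value = row[idx[col]]
            return "" if value is None else str(value)

        sites = [s for s in cell("introduced_sites").split(";") if s]
        record = PrimerRecord(
            gene_key=cell("gene_key"),
            locus=cell("locus"),
            primer_name=cell("primer_name"),
            primer_sequence=cell("primer_sequence"),
            introduced_sites=sites,
        )
        key = (record.gene_key, record.locus)
        if key in primers:
            raise ReferenceLoadError(f"duplicate primer key {key!r}")
        primers[key] = record
    wb.close()
    return primers


def write_primer_table(primers: dict[tuple[str, str], PrimerRecord], path: str | Path) -> None:
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(list(PRIMER_COLUMNS))
    for record in primers.values():
        ws.append(
            [
                record.gene_key,
                record.locus,
                record.primer_name,
                record.primer_sequence,
                ";".join(record.introduced_sites),
            ]
        )
    wb.save(str(path))
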