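"""Deterministic synthetic test surface: germline references, rearranged
reads with known truth, and plasmid variants with planted edits.

The generator exists so the whole pipeline can be exercised — and its
error rates measured against known ground truth — with zero downloads.
The germline genes are synthetic (random codon sequences with valid CDR3
anchor codons), not real alleles: V genes are generated pairwise highly
divergent so the best germline hit is unambiguous by construction, which
is what turns "the annotator recovered the planted truth" into a sharp,
assertable statement.

Everything is driven by explicit integer seeds; the same seed gives
byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from igkit import align as _al
from igkit.config import Config
from igkit.model import (
    AntibodyRecord,
    ConstantRegion,
    GermlineGene,
    GermlineReference,
    PrimerRecord,
    RestrictionEnzyme,
    SangerRead,
    SyntheticTruth,
)
from igkit.reference import (
    BUILTIN_ENZYMES,
    write_constants,
    write_germline_db,
    write_primer_table,
)
from igkit.seqio import write_database

NON_STOP_CODONS = tuple(
    sorted(c for c in _al.CODON_TABLE if _al.CODON_TABLE[c] != "*")
)

V_CODONS = 90  # germline V length: 90 codons, 2nd-CYS at codon 88
CYS_CODON_INDEX = 88
CYS_OFFSET = 3 * CYS_CODON_INDEX
J_PREFIX_CODONS = 3  # codons ahead of the J anchor (part of the CDR3 loop)
J_ANCHOR_OFFSET = 3 * J_PREFIX_CODONS
J_SUFFIX_CODONS = 10
CONSTANT_LEN = 150
CONSTANT_PREFIX_LEN = 80  # how much constant region a rearranged read carries
SHM_EDGE_MARGIN = 6  # planted mutations stay clear of V termini (see docs)

_LOCUS_PLAN = {
    "heavy": {"v_families": 6, "prefix_v": "IGHV", "prefix_j": "IGHJ", "n_j": 3,
              "anchor_codons": ("TGG",), "sites": ["AgeI", "SalI"]},
    "kappa": {"v_families": 4, "prefix_v": "IGKV", "prefix_j": "IGKJ", "n_j": 2,
              "anchor_codons": ("TTT", "TTC"), "sites": ["AgeI", "BsiWI"]},
    "lambda": {"v_families": 3, "prefix_v": "IGLV", "prefix_j": "IGLJ", "n_j": 2,
               "anchor_codons": ("TTT", "TTC"), "sites": ["AgeI", "XhoI"]},
}

HEAVY_ISOTYPES = ("IgM", "IgG", "IgA")


@dataclass
class Fixture:
    """A complete in-memory reference set plus the seed that built it."""

    db: GermlineReference
    constants: list[ConstantRegion]
    primers: dict[tuple[str, str], PrimerRecord]
    enzymes: dict[str, RestrictionEnzyme] = field(default_factory=lambda: dict(BUILTIN_ENZYMES))
    seed: int = 0

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "germline": out / "germline.fasta",
            "constants": out / "constants.fasta",
            "primers": out / "primers.xlsx",
        }
        write_germline_db(self.db, paths["germline"])
        write_constants(self.constants, paths["constants"])
        write_primer_table(self.primers, paths["primers"])
        return paths


def _random_codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(NON_STOP_CODONS) for _ in range(n))


def _global_identity(a: str, b: str) -> float:
    aligner = _al.make_aligner("global")
    aln = _al.align_pairwise(aligner, a, b)
    _, _, _, identity = _al.alignment_stats(aln, a, b)
    return identity


def _make_v_gene(rng: random.Random, name: str, locus: str) -> GermlineGene:
    body = _random_codons(rng, CYS_CODON_INDEX)
    cys = rng.choice(("TGT", "TGC"))
    tail = _random_codons(rng, V_CODONS - CYS_CODON_INDEX - 1)
    return GermlineGene(
        name=name, locus=locus, segment="V", sequence=body + cys + tail,
        reading_frame_offset=0, cys104_offset=CYS_OFFSET,
    )


def _make_j_gene(rng: random.Random, name: str, locus: str, anchors: tuple[str, ...]) -> GermlineGene:
    prefix = _random_codons(rng, J_PREFIX_CODONS)
    anchor = rng.choice(anchors)
    suffix = _random_codons(rng, J_SUFFIX_CODONS)
    return GermlineGene(
        name=name, locus=locus, segment="J", sequence=prefix + anchor + suffix,
        reading_frame_offset=0, anchor_offset=J_ANCHOR_OFFSET,
    )


def make_germline_fixture(seed: int = 0, max_pairwise_identity: float = 0.85) -> Fixture:
    """Build the miniature germline/constant/primer reference set.

    V genes are regenerated until every within-fixture pair stays at or
    below ``max_pairwise_identity`` under global alignment, so the best
    hit is never ambiguous for the substitution rates the generator
    plants.
    """
    rng = random.Random(seed)
    genes: list[GermlineGene] = []
    v_sequences: list[str] = []
    for locus, plan in _LOCUS_PLAN.items():
        for fam in range(1, plan["v_families"] + 1):
            name = f"{plan['prefix_v']}{fam}-S1"
            for _attempt in range(100):
                gene = _make_v_gene(rng, name, locus)
                if all(
                    _global_identity(gene.sequence, other) <= max_pairwise_identity
                    for other in v_sequences
                ):
                    break
            else:  # pragma: no cover - vanishingly unlikely with random codons
                raise RuntimeError("could not generate a divergent V gene")
            v_sequences.append(gene.sequence)
            genes.append(gene)
        for jn in range(1, plan["n_j"] + 1):
            genes.append(_make_j_gene(rng, f"{plan['prefix_j']}{jn}", locus, plan["anchor_codons"]))
    for dn in (1, 2):
        genes.append(
            GermlineGene(
                name=f"IGHD{dn}", locus="heavy", segment="D",
                sequence="".join(rng.choice("ACGT") for _ in range(15)),
            )
        )
    db = GermlineReference(genes)

    constants = [
        ConstantRegion(label, _random_codons(rng, CONSTANT_LEN // 3))
        for label in ("IgM", "IgG", "IgA", "kappa", "lambda")
    ]

    primers: dict[tuple[str, str], PrimerRecord] = {}
    for locus, plan in _LOCUS_PLAN.items():
        for fam in range(1, plan["v_families"] + 1):
            family = f"{plan['prefix_v']}{fam}"
            gene = db[f"{family}-S1"]
            primers[(family, locus)] = PrimerRecord(
                gene_key=family, locus=locus, primer_name=f"{family}-fwd",
                primer_sequence=gene.sequence[:21], introduced_sites=list(plan["sites"]),
            )
    return Fixture(db=db, constants=constants, primers=primers, seed=seed)


def _plant_substitutions(
    rng: random.Random, sequence: str, n: int, lo: int, hi: int
) -> tuple[str, list[int]]:
    """Plant ``n`` substitutions at distinct positions in [lo, hi) that never
    create a stop codon in the frame-0 translation."""
    seq = list(sequence)
    positions = sorted(rng.sample(range(lo, hi), n))
    for pos in positions:
        codon_start = 3 * (pos // 3)
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for base in choices:
            codon = seq[codon_start:codon_start + 3]
            codon[pos - codon_start] = base
            if _al.translate_codon("".join(codon)) != "*":
                seq[pos] = base
                break
        else:  # pragma: no cover - every codon has a non-stop single-base variant
            raise RuntimeError("no stop-free substitution available")
    return "".join(seq), positions


def make_rearrangement(
    fixture: Fixture,
    locus: str,
    n_shm: int,
    seed: int,
    mab_id: str = "mab001",
    isotype: str | None = None,
    embed_d: bool = True,
) -> tuple[SangerRead, SyntheticTruth]:
    """Build one rearranged read: mutated V + junction insert + J + constant.

    The junction insert is three codons (optionally seeded with six nt of
    a D gene on the heavy chain) chosen so the CYS..W/F junction
    translates without stops; SHM substitutions go into the V interior
    only (never the terminal 6 nt or the CYS codon), which keeps the
    planted count exactly recoverable by alignment.
    """
    rng = random.Random(seed)
    plan = _LOCUS_PLAN[locus]
    v = fixture.db[f"{plan['prefix_v']}{rng.randrange(plan['v_families']) + 1}-S1"]
    j = fixture.db[f"{plan['prefix_j']}{rng.randrange(plan['n_j']) + 1}"]
    d = None
    if locus == "heavy" and embed_d:
        d = fixture.db[f"IGHD{rng.randrange(2) + 1}"]

    v_mut, positions = _plant_substitutions(
        rng, v.sequence, n_shm, SHM_EDGE_MARGIN, CYS_OFFSET
    )

    for _attempt in range(100):
        if d is not None:
            off = rng.randrange(len(d.sequence) - 6 + 1)
            frag = d.sequence[off : off + 6]
            insert = rng.choice(NON_STOP_CODONS) + frag
        else:
            insert = _random_codons(rng, 3)
        junction = v_mut[CYS_OFFSET:] + insert + j.sequence[: J_ANCHOR_OFFSET + 3]
        if "*" not in _al.translate(junction):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build a stop-free junction")

    if locus == "heavy":
        label = isotype or HEAVY_ISOTYPES[rng.randrange(len(HEAVY_ISOTYPES))]
    else:
        label = locus
    const = next(c for c in fixture.constants if c.isotype_label == label)

    nucleotides = v_mut + insert + j.sequence + const.sequence[:CONSTANT_PREFIX_LEN]
    qualities = [rng.randint(35, 50) for _ in nucleotides]
    read = SangerRead(read_id=mab_id, nucleotides=nucleotides, qualities=qualities)

    anchor_read = len(v_mut) + len(insert) + J_ANCHOR_OFFSET
    junction_nt = nucleotides[CYS_OFFSET : anchor_read + 3]
    cdr3 = _al.translate(junction_nt)[1:-1]
    truth = SyntheticTruth(
        mab_id=mab_id, locus=locus, true_v=v.name, true_j=j.name,
        true_d=d.name if d else None, planted_shm=n_shm, shm_positions=positions,
        true_cdr3_aa=cdr3, true_isotype=label, seed=seed,
    )
    return read, truth


#: Edit kinds understood by :func:`make_plasmid_variant` and their expected verdicts.
EDIT_KINDS = {
    "none": "green",
    "silent": "green",
    "missense": "red",
    "nonsense": "red",
    "indel": "red",
    "missense_lowq": "brown",
}


def _window_bounds(amplicon: SangerRead, primer_nt: int = 25) -> tuple[int, int]:
    """Interior of the compared V..J window (read layout is generator-known)."""
    j_end = len(amplicon) - CONSTANT_PREFIX_LEN
    return primer_nt + 2, j_end - primer_nt - 3


def _pick_codon(rng: random.Random, lo: int, hi: int) -> int:
    """A codon index whose three bases lie fully inside [lo, hi)."""
    first = (lo + 2) // 3
    last = (hi - 3) // 3
    return rng.randint(first, last)


def make_plasmid_variant(
    amplicon: SangerRead,
    truth: SyntheticTruth,
    edit_kind: str,
    seed: int,
) -> tuple[SangerRead, SyntheticTruth]:
    """Clone the amplicon into a synthetic plasmid read, applying one edit plan.

    Edits are planted strictly inside the compared window and outside the
    primer-binding margins, so the expected verdict follows mechanically
    from the edit kind: none/silent -> green, missense/nonsense/indel ->
    red, missense under a Phred-8 quality window -> brown.
    """
    if edit_kind not in EDIT_KINDS:
        raise ValueError(f"unknown edit kind {edit_kind!r}")
    rng = random.Random(seed)
    seq = list(amplicon.nucleotides)
    qualities = [rng.randint(35, 50) for _ in seq]
    lo, hi = _window_bounds(amplicon)
    # Stay within the V body: junction edits would also be legitimate, but the
    # V body guarantees frame-0 codons without extra bookkeeping.
    hi = min(hi, CYS_OFFSET)
    edits: list[tuple[str, int, str, str]] = []

    def apply_substitution(want: str) -> tuple[int, str, str]:
        for _attempt in range(200):
            ci = _pick_codon(rng, lo, hi)
            start = 3 * ci
            codon = "".join(seq[start:start + 3])
            aa_old = _al.translate_codon(codon)
            offsets = [0, 1, 2]
            rng.shuffle(offsets)
            bases = list("ACGT")
            for off in offsets:
                rng.shuffle(bases)
                for base in bases:
                    if base == codon[off]:
                        continue
                    new = codon[:off] + base + codon[off + 1:]
                    aa_new = _al.translate_codon(new)
                    if want == "silent" and aa_new == aa_old and aa_new != "*":
                        seq[start + off] = base
                        return start + off, codon[off], base
                    if want == "missense" and aa_new not in (aa_old, "*"):
                        seq[start + off] = base
                        return start + off, codon[off], base
                    if want == "nonsense" and aa_new == "*" and aa_old != "*":
                        seq[start + off] = base
                        return start + off, codon[off], base
        raise RuntimeError(f"could not plant a {want} edit")  # pragma: no cover

    if edit_kind in ("silent",):
        pos, before, after = apply_substitution("silent")
        edits.append(("silent", pos, before, after))
    elif edit_kind in ("missense", "missense_lowq"):
        pos, before, after = apply_substitution("missense")
        edits.append((edit_kind, pos, before, after))
        if edit_kind == "missense_lowq":
            for q in range(max(0, pos - 5), min(len(qualities), pos + 6)):
                qualities[q] = 8
    elif edit_kind == "nonsense":
        pos, before, after = apply_substitution("nonsense")
        edits.append(("nonsense", pos, before, after))
    elif edit_kind == "indel":
        pos = rng.randrange(lo, hi)
        if rng.random() < 0.5:
            before = seq[pos]
            del seq[pos]
            del qualities[pos]
            edits.append(("indel", pos, before, "-"))
        else:
            base = rng.choice("ACGT")
            seq.insert(pos, base)
            qualities.insert(pos, rng.randint(35, 50))
            edits.append(("indel", pos, "-", base))

    plasmid = SangerRead(
        read_id=f"{truth.mab_id}_plasmid", nucleotides="".join(seq), qualities=qualities
    )
    new_truth = SyntheticTruth(
        **{**truth.__dict__, "edits": edits, "expected_verdict": EDIT_KINDS[edit_kind],
           "seed": seed}
    )
    return plasmid, new_truth


def _write_fastq(read: SangerRead, path: Path) -> None:
    rec = SeqRecord(Seq(read.nucleotides), id=read.read_id, description="")
    rec.letter_annotations["phred_quality"] = list(read.qualities)
    SeqIO.write([rec], str(path), "fastq")


@dataclass
class Benchmark:
    root: Path
    truth: pd.DataFrame
    paths: dict[str, Path]


def make_benchmark(
    out_dir: str | Path,
    n_pairs: int = 50,
    mix: dict[str, float] | None = None,
    seed: int = 7,
    config: Config | None = None,
) -> Benchmark:
    """Emit a ready-to-run dataset exercising the full annotate->compare path.

    Produces reference files, per-chain amplicon and plasmid FASTQ
    directories, a tracking .xlsx and a machine-readable truth table
    (TSV).  The verdict-class mix is a seeded multinomial draw whose
    realized counts are recorded in the truth table.
    """
    mix = mix or {"green": 0.6, "red": 0.3, "brown": 0.1}
    rng = random.Random(seed)
    root = Path(out_dir)
    (root / "amplicons").mkdir(parents=True, exist_ok=True)
    (root / "plasmids").mkdir(parents=True, exist_ok=True)

    fixture = make_germline_fixture(seed)
    paths = fixture.write(root)

    verdict_to_kinds = {
        "green": ["none", "silent"],
        "red": ["missense", "nonsense", "indel"],
        "brown": ["missense_lowq"],
    }
    classes = sorted(mix)
    weights = [mix[c] for c in classes]
    loci = ("heavy", "kappa", "lambda")

    rows = []
    records = []
    for i in range(n_pairs):
        mab_id = f"mab{i + 1:04d}"
        verdict_class = rng.choices(classes, weights=weights)[0]
        kind = rng.choice(verdict_to_kinds[verdict_class])
        locus = loci[i % len(loci)]
        n_shm = rng.randint(0, 8)
        pair_seed = rng.randrange(2**31)
        read, truth = make_rearrangement(fixture, locus, n_shm, pair_seed, mab_id=mab_id)
        plasmid, truth = make_plasmid_variant(read, truth, kind, pair_seed + 1)
        _write_fastq(read, root / "amplicons" / f"{mab_id}_{locus}.fastq")
        _write_fastq(plasmid, root / "plasmids" / f"{mab_id}_{locus}.fastq")
        records.append(AntibodyRecord(mab_id=mab_id, metadata={"plate": "P1", "well": f"W{i+1}"}))
        rows.append(
            {
                "mab_id": mab_id, "chain": locus, "true_v": truth.true_v,
                "true_j": truth.true_j, "true_d": truth.true_d or "",
                "planted_shm": truth.planted_shm, "true_cdr3_aa": truth.true_cdr3_aa,
                "true_isotype": truth.true_isotype, "edit_kind": kind,
                "expected_verdict": truth.expected_verdict, "seed": truth.seed,
            }
        )

    paths["database"] = root / "records.xlsx"
    write_database(records, paths["database"], columns=["mab_id", "plate", "well"])
    truth_df = pd.DataFrame(rows)
    paths["truth"] = root / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    paths["amplicons"] = root / "amplicons"
    paths["plasmids"] = root / "plasmids"
    return Benchmark(root=root, truth=truth_df, paths=paths)
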