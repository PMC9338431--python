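"""Sequence I/O, genetic-code tables, translation, and reading-frame intactness.

The central biological fact exploited throughout the package is that the
vertebrate mitochondrial genetic code differs from the standard nuclear code
at exactly four codons (AGA, AGG, ATA, TGA).  A mitochondrial gene copied
into the nucleus therefore typically contains premature stop codons when read
with the nuclear code, while its *mitochondrial* reading frame may remain
intact.  :func:`classify_reading_frame` formalises that test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "VERTEBRATE_MITO_CODE",
    "SeqRecord",
    "IntactnessReport",
    "read_fasta",
    "write_fasta",
    "translate",
    "reverse_complement",
    "classify_reading_frame",
    "write_intervals",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the format or contains duplicates."""


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: 64 codons -> amino acid, with an explicit stop set."""

    name: str
    table: dict  # codon -> one-letter amino acid; stops map to '*'
    stops: frozenset

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError(f"genetic code {self.name!r} must map all 64 codons")
        if not self.stops <= set(self.table):
            raise ValueError("stop codons must be table keys")

    @classmethod
    def from_ncbi_id(cls, table_id: int, name: str | None = None) -> "GeneticCode":
        ct = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ct.forward_table)
        for stop in ct.stop_codons:
            table[stop] = "*"
        return cls(name=name or ct.names[0], table=table, stops=frozenset(ct.stop_codons))

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stops

    @property
    def sense_codons(self) -> list:
        """Lexicographically sorted non-stop codons (61 standard, 60 vert-mito)."""
        return sorted(c for c in self.table if c not in self.stops)


STANDARD_CODE = GeneticCode.from_ncbi_id(1, "standard")
VERTEBRATE_MITO_CODE = GeneticCode.from_ncbi_id(2, "vertebrate_mitochondrial")


@dataclass
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}; ``circular`` marks mitogenomes."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r} contains non-DNA symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class IntactnessReport:
    """Outcome of testing a numt fragment against a mitochondrial gene."""

    gene_id: str
    frame: int
    mito_internal_stops: int
    nuclear_internal_stops: int
    gap_free: bool
    intact_mito_frame: bool
    no_homology: bool = False
    n_substitutions: int = 0
    aligned_gene_start: int = 0  # 1-based inclusive, gene coordinates
    aligned_gene_end: int = 0
    aligned_fragment_start: int = 0
    aligned_fragment_end: int = 0


def read_fasta(path) -> list:
    """Read a (wrapped or unwrapped) multi-FASTA into :class:`SeqRecord` objects.

    Duplicate record ids and empty sequences are parse errors naming the
    offending record.
    """
    records = []
    seen = set()
    dupes = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                dupes.append(rec.id)
                continue
            seen.add(rec.id)
            records.append(SeqRecord(id=rec.id, seq=str(rec.seq)))
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    if dupes:
        raise FastaParseError(f"duplicate FASTA ids: {sorted(set(dupes))}")
    if not records:
        # distinguish empty/malformed from a valid empty parse of junk text
        text = Path(path).read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise FastaParseError(f"{path}: not FASTA (no '>' header)")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70):
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, code: GeneticCode, frame: int = 0) -> str:
    """Translate ``seq`` in ``frame`` (0/1/2); stops render as '*', N-codons as 'X'.

    The trailing incomplete codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    s = seq.upper()
    out = []
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        out.append(code.table.get(codon, "X"))
    return "".join(out)


def _frame_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def classify_reading_frame(
    fragment_seq: str,
    mito_gene_seq: str,
    gene_id: str = "gene",
    min_identity: float = 0.6,
    min_block: int | None = None,
    require_full_gene: bool = False,
) -> IntactnessReport:
    """Test whether a numt fragment carries an intact mitochondrial reading frame.

    The fragment is locally aligned to the gene (match +1, mismatch -1, gap
    open -5, extend -2) so that flanking non-homologous sequence is ignored;
    the aligned block is then read in the gene's codon frame under both the
    vertebrate-mitochondrial and standard nuclear codes.  ``intact_mito_frame``
    requires a gap-free block with zero internal mitochondrial stops; the
    gene's own terminal stop codon never counts as premature.

    With ``require_full_gene`` the entire gene must align gap-free; by default
    only the overlapping segment is assessed.
    """
    fragment_seq = fragment_seq.upper()
    mito_gene_seq = mito_gene_seq.upper()
    if not fragment_seq or not mito_gene_seq:
        raise ValueError("fragment and gene sequences must be non-empty")

    no_hom = IntactnessReport(
        gene_id=gene_id, frame=0, mito_internal_stops=0, nuclear_internal_stops=0,
        gap_free=False, intact_mito_frame=False, no_homology=True,
    )
    aligner = _frame_aligner()
    try:
        aln = aligner.align(mito_gene_seq, fragment_seq)[0]
    except (IndexError, ValueError):
        return no_hom

    gene_blocks, frag_blocks = aln.aligned
    if len(gene_blocks) == 0:
        return no_hom
    gene_lo, gene_hi = gene_blocks[0][0], gene_blocks[-1][1]  # 0-based half-open
    frag_lo, frag_hi = frag_blocks[0][0], frag_blocks[-1][1]
    gap_free = len(gene_blocks) == 1

    # identity over aligned columns (matches / aligned-block columns)
    matches = sum(
        1
        for (gs, ge), (fs, fe) in zip(gene_blocks, frag_blocks)
        for g, f in zip(mito_gene_seq[gs:ge], fragment_seq[fs:fe])
        if g == f
    )
    n_cols = sum(ge - gs for gs, ge in gene_blocks)
    if min_block is None:
        min_block = min(len(mito_gene_seq), 30)
    if n_cols < min_block or matches / n_cols < min_identity:
        return no_hom
    if require_full_gene and (gene_lo != 0 or gene_hi != len(mito_gene_seq)):
        gap_free = False

    frame = gene_lo % 3  # offset of block start within the gene's codon frame

    # read the fragment block in the gene's frame; count stops per code
    mito_stops = nuc_stops = 0
    n_subs = 0
    last_codon_start = (len(mito_gene_seq) // 3 - 1) * 3  # gene's terminal codon
    if gap_free:
        block_gene = range(gene_lo, gene_hi)
        frag_block = fragment_seq[frag_lo:frag_hi]
        gene_block = mito_gene_seq[gene_lo:gene_hi]
        n_subs = sum(1 for a, b in zip(frag_block, gene_block) if a != b)
        # first complete codon boundary inside the block, gene coordinates
        start = gene_lo + ((3 - gene_lo % 3) % 3)
        for g in range(start, gene_hi - 2, 3):
            codon = frag_block[g - gene_lo : g - gene_lo + 3]
            if g == last_codon_start:
                continue  # the gene's own stop is not premature
            if VERTEBRATE_MITO_CODE.is_stop(codon):
                mito_stops += 1
            if STANDARD_CODE.is_stop(codon):
                nuc_stops += 1
    else:
        for (gs, ge), (fs, fe) in zip(gene_blocks, frag_blocks):
            n_subs += sum(
                1 for a, b in zip(mito_gene_seq[gs:ge], fragment_seq[fs:fe]) if a != b
            )

    intact = gap_free and mito_stops == 0
    return IntactnessReport(
        gene_id=gene_id,
        frame=frame,
        mito_internal_stops=mito_stops,
        nuclear_internal_stops=nuc_stops,
        gap_free=gap_free,
        intact_mito_frame=intact,
        no_homology=False,
        n_substitutions=n_subs,
        aligned_gene_start=gene_lo + 1,
        aligned_gene_end=gene_hi,
        aligned_fragment_start=frag_lo + 1,
        aligned_fragment_end=frag_hi,
    )


def write_intervals(numts: Sequence, path, fmt: str = "TSV"):
    """Write numt intervals as BED6 (0-based half-open), GFF3 or TSV (1-based).

    The TSV mirrors the discovery summary table: scaffold, start, end,
    chromosome label, fragment count, total length and mitochondrial
    coordinates.  Output rows are sorted by scaffold then start.
    """
    fmt = fmt.upper()
    if fmt not in {"BED", "GFF3", "TSV"}:
        raise ValueError(f"unknown format {fmt!r}; supported: BED, GFF3, TSV")
    items = sorted(numts, key=lambda n: (_natural_key(n.scaffold), n.span_start))
    lines = []
    if fmt == "BED":
        for n in items:
            lines.append(
                f"{n.scaffold}\t{n.span_start - 1}\t{n.span_end}\t{n.id}\t0\t{n.strand}"
            )
    elif fmt == "GFF3":
        lines.append("##gff-version 3")
        for n in items:
            attrs = f"ID={n.id};n_fragments={len(n.fragments)}"
            lines.append(
                f"{n.scaffold}\tnumtforge\tnumt\t{n.span_start}\t{n.span_end}"
                f"\t.\t{n.strand}\t.\t{attrs}"
            )
    else:
        lines.append(
            "numt_id\tscaffold\tstart\tend\tchromosome\tn_fragments"
            "\tnumt_length\tmito_coordinates"
        )
        for n in items:
            mito = "; ".join(f"{s}-{e}" for s, e in n.mito_coordinate_list)
            chrom = getattr(n, "chromosome", n.scaffold)
            lines.append(
                f"{n.id}\t{n.scaffold}\t{n.span_start}\t{n.span_end}\t{chrom}"
                f"\t{len(n.fragments)}\t{n.total_length}\t{mito}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def _natural_key(s: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]


def bed_to_internal(start: int, end: int) -> tuple:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end
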