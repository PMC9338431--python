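"""Generators for mitonuclear test genomes with known insertion histories.

Every input the pipeline consumes can be produced here with ground truth
attached: a circular mitogenome carrying 13 protein-coding genes laid out
like a vertebrate mtDNA, nuclear scaffolds with planted numt insertions of
controlled age, fragmentation, strand and donor lineage, and codon
alignments simulated under the GY94 selection models.

Insertion sources mirror the biological scenarios of interest:

* ``canonical``      — the reference mitogenome itself is the donor;
* ``heteroplasmic``  — a divergent mtDNA variant co-existing within the
  species donates the copy;
* ``hybrid``         — mtDNA introgressed from a related species donates it.

For the two noncanonical sources the donor first evolves away from the
reference under purifying selection (substitutions creating in-frame stop
codons inside genes are rejected and nonsynonymous changes are suppressed),
because the donor molecule was a functional mitochondrial genome up to the
moment of insertion.  After insertion the copy evolves neutrally at the
nuclear rate: every site is equally mutable and reading frames decay freely.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio_codes import (
    SeqRecord,
    VERTEBRATE_MITO_CODE,
    reverse_complement,
    translate,
)
from .selection_models import CodonMSA, CodonStates, ModelParams, CodonModelSpec, \
    build_rate_matrix, _transition_matrix_factory
from .phylo import NUMT, TreeNode

__all__ = [
    "OTARIOID_STUDY_TREE",
    "GeneAnnotation",
    "MitogenomeConfig",
    "InsertionEvent",
    "SimulatedDataset",
    "simulate_mitogenome",
    "simulate_numt_landscape",
    "simulate_codon_alignment",
    "default_landscape_events",
    "default_landscape",
    "write_gff3",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Reference topology for selection-model studies: a clade of five numt copies
# (one per otarioid lineage carrying the insertion) against three
# mitochondrial reference sequences.  Branch lengths are substitutions/codon,
# sized for an insertion tens of Myr old so that clade-specific omegas are
# estimable from alignments of a few hundred codons.
OTARIOID_STUDY_TREE = (
    "(((ag#numt:0.08,(zc#numt:0.06,ej#numt:0.06)#numt:0.05)#numt:0.08,"
    "(cu#numt:0.09,or#numt:0.12)#numt:0.06)#numt:0.15,"
    "(mt1:0.25,mt2:0.2):0.1,mt3:0.3);"
)

# approximate vertebrate mitochondrial protein-coding gene lengths (bp,
# including the stop codon), in genome order
DEFAULT_GENE_LENGTHS = {
    "ND1": 957, "ND2": 1044, "COX1": 1545, "COX2": 684, "ATP8": 204,
    "ATP6": 681, "COX3": 783, "ND3": 348, "ND4L": 297, "ND4": 1377,
    "ND5": 1821, "ND6": 528, "CYTB": 1140,
}


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class MitogenomeConfig:
    total_length: int = 16500
    gene_lengths: tuple = tuple(DEFAULT_GENE_LENGTHS.items())
    leading_rrna: int = 1600   # stands in for the 12S/16S block
    spacer: int = 70           # tRNA-sized inter-gene spacers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """A stop-free ORF under the vertebrate mito code: ATG ... sense ... TAA."""
    if length % 3 or length < 9:
        raise ValueError("gene length must be a multiple of 3 and >= 9")
    sense = [c for c in VERTEBRATE_MITO_CODE.sense_codons if c != "ATG"]
    n_mid = length // 3 - 2
    mid = rng.choice(len(sense), size=n_mid)
    return "ATG" + "".join(sense[i] for i in mid) + "TAA"


def simulate_mitogenome(
    config: MitogenomeConfig = MitogenomeConfig(), seed: int = 0
):
    """Simulate a circular mitogenome; returns (SeqRecord, [GeneAnnotation]).

    Genes are guaranteed stop-free ORFs under the vertebrate mitochondrial
    code; the remainder is random sequence standing in for rRNA/tRNA blocks
    and the D-loop, which pads the genome to ``total_length``.
    """
    rng = np.random.default_rng([seed, 0])  # stream decorrelated from the landscape's
    genes = dict(config.gene_lengths)
    needed = config.leading_rrna + sum(genes.values()) + config.spacer * len(genes)
    if needed > config.total_length:
        raise ValueError(
            f"gene layout needs {needed} bp but genome is {config.total_length} bp"
        )
    parts = [_random_seq(rng, config.leading_rrna)]
    pos = config.leading_rrna
    annotations = []
    for name, length in genes.items():
        parts.append(_random_seq(rng, config.spacer))
        pos += config.spacer
        orf = _random_orf(rng, length)
        annotations.append(GeneAnnotation(name, pos + 1, pos + length))
        parts.append(orf)
        pos += length
    parts.append(_random_seq(rng, config.total_length - pos))  # D-loop + padding
    record = SeqRecord(id="mito", seq="".join(parts), circular=True)
    assert all(
        "*" not in translate(record.seq[a.start - 1 : a.end - 3], VERTEBRATE_MITO_CODE)
        for a in annotations
    )
    return record, annotations


def write_gff3(annotations, path, seqid: str = "mito"):
    lines = ["##gff-version 3"]
    for a in annotations:
        lines.append(
            f"{seqid}\tnumtforge\tCDS\t{a.start}\t{a.end}\t.\t{a.strand}\t0"
            f"\tID={a.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# numt landscape


@dataclass
class InsertionEvent:
    """One planted mitonuclear insertion with full ground truth.

    ``age`` is the expected substitutions/site accumulated after insertion
    (neutral, all sites); ``donor_divergence`` separates the donor mtDNA from
    the reference before insertion (constrained, synonymous-biased).
    ``mito_intervals`` are 1-based inclusive; an end beyond the mitogenome
    length wraps across the origin.  ``spacers`` holds the nuclear gap
    lengths between consecutive fragments (len(mito_intervals) - 1 entries).
    """

    source: str  # canonical | heteroplasmic | hybrid
    mito_intervals: list
    age: float = 0.0
    donor_divergence: float = 0.0
    strand: str = "+"
    spacers: list = field(default_factory=list)
    scaffold: str | None = None
    position: int | None = None  # 1-based insertion point in the background
    indels: bool = False
    # realized after simulation:
    realized_fragments: list = field(default_factory=list)  # (scaffold, start, end)

    def __post_init__(self):
        if self.source not in ("canonical", "heteroplasmic", "hybrid"):
            raise ValueError(f"unknown insertion source {self.source!r}")
        if self.age < 0 or self.donor_divergence < 0:
            raise ValueError("rates must be non-negative")
        if len(self.spacers) != max(len(self.mito_intervals) - 1, 0):
            raise ValueError("need one spacer length per inter-fragment gap")
        if self.source == "canonical" and self.donor_divergence > 0:
            raise ValueError("canonical insertions have donor_divergence 0")

    @property
    def n_fragments(self) -> int:
        return len(self.mito_intervals)

    @property
    def expected_single_numt(self) -> bool:
        return all(s < 10000 for s in self.spacers)


@dataclass
class SimulatedDataset:
    mito: SeqRecord
    annotations: list
    nuclear: list  # SeqRecord scaffolds
    events: list   # with realized_fragments filled in
    seed: int


def _evolve_donor(
    rng, seq: str, annotations, divergence: float, nonsyn_acceptance: float = 0.15
) -> str:
    """Evolve a functional mitogenome copy to a target divergence.

    Substitutions are proposed uniformly (strand-symmetric); inside annotated
    genes, proposals creating an in-frame stop codon under the mitochondrial
    code are rejected outright and other nonsynonymous changes are accepted
    with low probability, emulating purifying selection on the organellar
    donor.
    """
    if divergence == 0:
        return seq
    arr = bytearray(seq.encode())
    target = round(divergence * len(seq))
    gene_of = {}
    for a in annotations:
        for p in range(a.start - 1, a.end):
            gene_of[p] = a
    applied = 0
    guard = 0
    while applied < target and guard < 200 * target + 1000:
        guard += 1
        p = int(rng.integers(len(arr)))
        old = arr[p]
        new = int(rng.choice(_BASES[_BASES != old]))
        ann = gene_of.get(p)
        if ann is not None:
            off = p - (ann.start - 1)
            cstart = p - off % 3
            codon = bytes(arr[cstart : cstart + 3])
            mutant = bytearray(codon)
            mutant[p - cstart] = new
            mutant = bytes(mutant).decode()
            codon = codon.decode()
            is_terminal = cstart - (ann.start - 1) >= (ann.end - ann.start + 1) - 3
            if not is_terminal:
                if VERTEBRATE_MITO_CODE.is_stop(mutant):
                    continue
                if (
                    VERTEBRATE_MITO_CODE.table[mutant] != VERTEBRATE_MITO_CODE.table[codon]
                    and rng.random() > nonsyn_acceptance
                ):
                    continue
        arr[p] = new
        applied += 1
    return arr.decode()


def _mutate_neutral(rng, seq: str, rate: float, indels: bool = False) -> str:
    """Neutral post-insertion evolution: per-site substitution probability
    ``rate``; optional indels (rate 5% of substitutions, geometric mean 2)."""
    if rate == 0 and not indels:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for p in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    out = arr.tobytes().decode()
    if indels and rate > 0:
        n_indels = rng.binomial(len(out), 0.05 * rate)
        for _ in range(n_indels):
            p = int(rng.integers(len(out)))
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                out = out[:p] + out[p + length :]
            else:
                out = out[:p] + _random_seq(rng, length) + out[p:]
    return out


def _extract_interval(mito: SeqRecord, start: int, end: int) -> str:
    L = len(mito.seq)
    if end <= L:
        return mito.seq[start - 1 : end]
    if not mito.circular:
        raise ValueError("interval runs off a linear mitogenome")
    return mito.seq[start - 1 :] + mito.seq[: end - L]


def simulate_numt_landscape(
    mito: SeqRecord,
    annotations,
    events,
    seed: int = 0,
    n_scaffolds: int = 3,
    scaffold_length: int = 200_000,
    min_separation: int = 25_000,
) -> SimulatedDataset:
    """Plant insertion events into random nuclear scaffolds; returns the
    dataset with realized fragment coordinates recorded on each event.

    Events without an explicit scaffold/position are placed deterministically
    (from ``seed``) with at least ``min_separation`` bases between constructs;
    overlapping explicit placements raise.
    """
    rng = np.random.default_rng([seed, 1])
    scaffolds = {
        f"scaffold_{i + 1}": _random_seq(rng, scaffold_length)
        for i in range(n_scaffolds)
    }
    names = list(scaffolds)

    # build each construct: donor -> fragments (+spacers) -> neutral decay
    constructs = []
    for ev in events:
        donor_seq = (
            mito.seq
            if ev.source == "canonical"
            else _evolve_donor(rng, mito.seq, annotations, ev.donor_divergence)
        )
        donor = SeqRecord(id="donor", seq=donor_seq, circular=mito.circular)
        pieces = []
        frag_spans = []  # (offset, length) within construct
        offset = 0
        for k, (s, e) in enumerate(ev.mito_intervals):
            frag = _extract_interval(donor, s, e)
            if ev.strand == "-":
                frag = reverse_complement(frag)
            frag = _mutate_neutral(rng, frag, ev.age, ev.indels)
            frag_spans.append((offset, len(frag)))
            pieces.append(frag)
            offset += len(frag)
            if k < len(ev.mito_intervals) - 1:
                spacer = _random_seq(rng, ev.spacers[k])
                pieces.append(spacer)
                offset += len(spacer)
        constructs.append(("".join(pieces), frag_spans))

    # assign placements
    placements = []  # (scaffold, position, event_index)
    auto_cursor = {n: 20_000 for n in names}
    auto_scaffold = 0
    for i, ev in enumerate(events):
        clen = len(constructs[i][0])
        if ev.scaffold is not None and ev.position is not None:
            placements.append((ev.scaffold, ev.position, i))
            continue
        placed = False
        for _ in range(len(names)):
            name = names[auto_scaffold % len(names)]
            pos = auto_cursor[name]
            if pos + clen + min_separation < scaffold_length:
                placements.append((name, pos, i))
                auto_cursor[name] = pos + clen + min_separation + int(
                    rng.integers(0, 5000)
                )
                auto_scaffold += 1
                placed = True
                break
            auto_scaffold += 1
        if not placed:
            raise ValueError("scaffolds too small for the requested events")

    for name in names:
        evs = sorted(p for p in placements if p[0] == name)
        for (_, a, i), (_, b, j) in zip(evs, evs[1:]):
            if a + len(constructs[i][0]) > b:
                raise ValueError(f"overlapping planted insertions on {name}")

    # splice constructs into scaffolds (ascending position, tracking offsets)
    records = []
    for name in names:
        seq = scaffolds[name]
        offset = 0
        for _, pos, i in sorted(p for p in placements if p[0] == name):
            construct, frag_spans = constructs[i]
            insert_at = pos - 1 + offset
            seq = seq[:insert_at] + construct + seq[insert_at:]
            ev = events[i]
            ev.realized_fragments = [
                (name, insert_at + off + 1, insert_at + off + ln)
                for off, ln in frag_spans
            ]
            ev.scaffold = name
            offset += len(construct)
        records.append(SeqRecord(id=name, seq=seq))

    return SimulatedDataset(
        mito=mito, annotations=annotations, nuclear=records, events=list(events),
        seed=seed,
    )


def default_landscape_events() -> list:
    """The default study landscape: 12 insertions spanning the regimes of
    interest — lengths 250-14,000 bp, post-insertion divergence 0-0.12,
    both strands, one to four fragments, canonical and noncanonical donors.
    """
    iv = lambda s, l: [(s, s + l - 1)]
    return [
        InsertionEvent("canonical", iv(9566, 569), age=0.0),
        InsertionEvent(
            "canonical",
            [(2107, 4606), (7736, 9235), (5454, 8453), (11628, 12127)],
            age=0.02, spacers=[800, 1200, 400],
        ),
        InsertionEvent("canonical", iv(3018, 5000), age=0.12),
        InsertionEvent("canonical", iv(15767, 294), age=0.05),
        InsertionEvent(
            "hybrid", [(9871, 11748), (11733, 13078)],
            age=0.005, donor_divergence=0.05, spacers=[1500],
        ),
        InsertionEvent("heteroplasmic", iv(8175, 1743), donor_divergence=0.03),
        InsertionEvent("canonical", iv(1, 2801), age=0.03, strand="-"),
        InsertionEvent("canonical", iv(8723, 250), age=0.10),
        InsertionEvent(
            "canonical", [(74, 1616), (2968, 4007), (5120, 5471)],
            age=0.01, spacers=[9900, 9900],
        ),
        InsertionEvent(
            "canonical", [(104, 428), (1757, 2257)], age=0.08, spacers=[3000],
        ),
        InsertionEvent("canonical", iv(2000, 14000), age=0.0),
        InsertionEvent(
            "canonical", [(11396, 11907), (14387, 15304)],
            age=0.04, strand="-", spacers=[2500],
        ),
    ]


def default_landscape(seed: int = 0) -> SimulatedDataset:
    mito, annotations = simulate_mitogenome(seed=seed)
    return simulate_numt_landscape(
        mito, annotations, default_landscape_events(), seed=seed
    )


# ---------------------------------------------------------------------------
# codon alignments under the selection models


def simulate_codon_alignment(
    tree: TreeNode,
    spec: CodonModelSpec,
    params: ModelParams,
    n_codons: int,
    seed: int = 0,
    codon_freqs=None,
) -> CodonMSA:
    """Evolve codon sites along ``tree`` under the GY94 model of ``spec``.

    Site classes are drawn from ``params.proportions``; each branch uses the
    generator matching its class (background vs numt) and the site's class.
    Root states are drawn from the stationary distribution.  Returns the leaf
    sequences as a gap-free in-frame alignment; deterministic per seed.
    """
    if spec.uses_partition and all(
        b.branch_class != NUMT for b in tree.branches()
    ):
        raise ValueError(f"model {spec.kind!r} needs numt-labelled branches")
    st = CodonStates(spec.code)
    if codon_freqs is None:
        codon_freqs = np.full(st.n, 1.0 / st.n)
    codon_freqs = np.asarray(codon_freqs, float)
    rng = np.random.default_rng(seed)

    n_classes = len(params.proportions)
    site_class = rng.choice(n_classes, size=n_codons, p=params.proportions)

    factories = {}
    for k in range(n_classes):
        for tag, w in (("bg", params.omega_background[k]), ("numt", params.omega_numt[k])):
            key = (tag, round(float(w), 12))
            if key not in factories:
                q = build_rate_matrix(params.kappa, w, codon_freqs, spec.code)
                factories[key] = _transition_matrix_factory(q, codon_freqs)
            factories[(tag, k)] = factories[key]

    states = {id(tree): rng.choice(st.n, size=n_codons, p=codon_freqs)}
    order = [n for n in tree.postorder()][::-1]  # preorder
    for node in order:
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n_codons, dtype=np.int64)
        tag = "numt" if node.branch_class == NUMT else "bg"
        for k in range(n_classes):
            mask = site_class == k
            if not mask.any():
                continue
            pmat = factories[(tag, k)](node.length)
            cum = np.cumsum(pmat, axis=1)
            u = rng.random(int(mask.sum()))
            rows = parent_states[mask]
            child[mask] = (u[:, None] > cum[rows]).sum(axis=1)
        states[id(node)] = child

    names, seqs = [], []
    for leaf in tree.leaves():
        names.append(leaf.name)
        seqs.append("".join(st.codons[i] for i in states[id(leaf)]))
    return CodonMSA(names, seqs)
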