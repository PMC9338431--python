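"""Pairwise dN/dS between numt-resident genes and their mitochondrial homologs.

Counting follows Nei & Gojobori (1986): each codon position contributes
fractional synonymous/nonsynonymous *site* counts obtained by classifying all
single-nucleotide mutants, and codon pairs differing at several positions are
resolved by averaging over all mutational pathways that avoid stop codons.
Proportions are corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - 4p/3), and significance of dN != dS is assessed with a
Fisher exact test on the 2x2 substitution/site table.

Mutants that would create a stop codon are excluded from the site
denominators, so S + N is slightly below 3 x n_codons for codons adjacent to
stops — the classical NG86 convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from scipy import stats

from .seqio_codes import GeneticCode, STANDARD_CODE

__all__ = [
    "CodonAlignment",
    "SubstitutionSummary",
    "count_sites",
    "count_substitutions",
    "pairwise_dnds",
    "jukes_cantor",
]

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """A gap-free, in-frame pairwise alignment of two coding sequences.

    ``seq_a`` is the reference (functional mitochondrial) gene and must be
    free of internal stop codons under ``code``; the terminal stop codon, if
    present in both sequences, is trimmed on construction.
    """

    gene_id: str
    seq_a: str
    seq_b: str
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length must be divisible by 3")
        if self.seq_a and self.code.is_stop(self.seq_a[-3:]):
            self.seq_a = self.seq_a[:-3]
            self.seq_b = self.seq_b[:-3]
        for i in range(0, len(self.seq_a), 3):
            if self.code.is_stop(self.seq_a[i : i + 3]):
                raise ValueError(
                    f"reference sequence contains internal stop at codon {i // 3 + 1}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class SubstitutionSummary:
    """NG86 site and substitution counts with derived rates (one report row)."""

    gene_id: str
    syn_sites: float          # S
    nonsyn_sites: float       # N
    syn_subs: float           # Sd (pathway-averaged)
    nonsyn_subs: float        # Nd
    syn_subs_int: int         # minimal-path integer counts for reporting
    nonsyn_subs_int: int
    dn: float | None
    ds: float | None
    omega: float | None
    p_value: float | None
    saturated: bool = False
    excluded_codons: list = field(default_factory=list)

    @property
    def n_substitutions(self) -> float:
        return self.syn_subs + self.nonsyn_subs


def _single_mutants(codon: str):
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                yield pos, codon[:pos] + b + codon[pos + 1 :]


def count_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> tuple:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes 1 site split between the two categories by the
    fraction of its non-stop single-nucleotide mutants that are synonymous.
    """
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"{codon} is a stop codon under {code.name}")
    aa = code.table[codon]
    syn = 0.0
    for pos in range(3):
        muts = [codon[:pos] + b + codon[pos + 1 :] for b in _BASES if b != codon[pos]]
        valid = [m for m in muts if not code.is_stop(m)]
        if valid:
            syn += sum(1 for m in valid if code.table[m] == aa) / len(valid)
    return syn, 3.0 - syn


def _pair_step_counts(codon_a: str, codon_b: str, code: GeneticCode) -> tuple | None:
    """Pathway-averaged (syn, nonsyn) steps between two codons, or None.

    Averages over all orderings of the differing positions whose intermediate
    codons are all sense codons; returns None when every pathway passes
    through a stop.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != codon_b:
                ok = False
                break
            if code.is_stop(nxt):  # target itself is a stop: path invalid too
                ok = False
                break
            if code.table[nxt] == code.table[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        return None
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n


def _pair_minimal_counts(codon_a: str, codon_b: str, code: GeneticCode) -> tuple | None:
    """Integer (syn, nonsyn) steps along valid pathways; ties prefer synonymous."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0, 0
    best = None
    for order in itertools.permutations(diff):
        cur = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.table[nxt] == code.table[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok and (best is None or syn > best[0]):
            best = (syn, nonsyn)
    return best


def count_substitutions(aln: CodonAlignment) -> tuple:
    """(Sd, Nd, per-codon path records) over the alignment, NG86 averaging.

    Codon pairs whose every pathway crosses a stop codon are excluded and
    listed in the returned records with a None entry.
    """
    sd = nd = 0.0
    records = []
    for idx, (ca, cb) in enumerate(aln.codon_pairs()):
        if "N" in ca or "N" in cb:
            records.append((idx, ca, cb, None))
            continue
        counts = _pair_step_counts(ca, cb, aln.code)
        records.append((idx, ca, cb, counts))
        if counts is not None:
            sd += counts[0]
            nd += counts[1]
    return sd, nd, records


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(aln: CodonAlignment) -> SubstitutionSummary:
    """Full NG86 dN/dS summary for one gene pair (one report-table row).

    Sites are averaged over the two sequences; dN and dS use the
    Jukes-Cantor correction; omega = dN/dS is left undefined (None) when
    dS is zero or either rate saturates; the p-value is a two-sided Fisher
    exact test on the table [[Sd, S-Sd], [Nd, N-Nd]].
    """
    if aln.n_codons < 10:
        raise ValueError("need at least 10 codons for a meaningful dN/dS")
    s_sites = n_sites = 0.0
    excluded = []
    sd, nd, records = count_substitutions(aln)
    sd_int = nd_int = 0
    for idx, ca, cb, counts in records:
        if counts is None:
            excluded.append(idx)
            continue
        mini = _pair_minimal_counts(ca, cb, aln.code)
        if mini is not None:
            sd_int += mini[0]
            nd_int += mini[1]
        for codon in (ca, cb):
            if aln.code.is_stop(codon):
                # numt copy may have gained a stop; count its sites from the
                # reference partner so the denominator stays defined
                codon = ca
            s, n = count_sites(codon, aln.code)
            s_sites += s / 2.0
            n_sites += n / 2.0

    if s_sites == 0 or n_sites == 0:
        raise ValueError("degenerate alignment: no countable sites")
    ps = sd / s_sites
    pn = nd / n_sites
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    saturated = ds is None or dn is None

    if sd + nd == 0:
        # no observed substitutions: the report row stays empty, never 0/0
        return SubstitutionSummary(
            gene_id=aln.gene_id, syn_sites=s_sites, nonsyn_sites=n_sites,
            syn_subs=0.0, nonsyn_subs=0.0, syn_subs_int=0, nonsyn_subs_int=0,
            dn=None, ds=None, omega=None, p_value=1.0,
        )

    omega = None
    if not saturated and ds is not None and ds > 0 and dn is not None:
        omega = dn / ds

    table = [
        [sd, max(s_sites - sd, 0.0)],
        [nd, max(n_sites - nd, 0.0)],
    ]
    int_table = [[round(x) for x in row] for row in table]
    p_value = float(stats.fisher_exact(int_table, alternative="two-sided")[1])

    return SubstitutionSummary(
        gene_id=aln.gene_id,
        syn_sites=s_sites, nonsyn_sites=n_sites,
        syn_subs=sd, nonsyn_subs=nd,
        syn_subs_int=sd_int, nonsyn_subs_int=nd_int,
        dn=dn, ds=ds, omega=omega, p_value=p_value,
        saturated=saturated, excluded_codons=excluded,
    )
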