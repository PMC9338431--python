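"""Homology scan of a mitogenome against a nuclear genome and numt assembly.

The scanner is a classic seed-and-extend local search: exact word_size seeds
(default 20, the discovery setting used throughout the package) are indexed
over the mitochondrial query, located on both strands of every nuclear
scaffold, and extended along their diagonal with an X-dropoff rule under
blastn-like scores (+2/-3).  Hits are assigned Karlin-Altschul e-values,
filtered on the "> 200 bp" length rule, and fragments falling within 10 kb of
one another on a scaffold are clustered into a single numt insertion.

Ungapped extension is exact for substitution-only divergence; insertions that
have additionally accumulated indels surface as several collinear fragments,
which the 10 kb clustering reunites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio_codes import SeqRecord, reverse_complement, _natural_key

__all__ = [
    "HomologyHit",
    "Numt",
    "ConservationProfile",
    "scan",
    "filter_hits",
    "cluster_fragments",
    "profile_conservation",
]

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_XDROP = 100
KA_K = 0.3  # Karlin-Altschul K; documented constant for +2/-3 nucleotide scores


@dataclass
class HomologyHit:
    """One local alignment between the mitogenome and a nuclear scaffold.

    All coordinates are 1-based inclusive; nuclear coordinates always refer
    to the forward strand of the scaffold, with ``strand`` recording the
    orientation of the mitochondrial match.
    """

    nuclear_scaffold: str
    nuclear_start: int
    nuclear_end: int
    strand: str
    mito_start: int
    mito_end: int
    percent_identity: float
    aligned_length: int
    bit_score: float
    e_value: float

    def __post_init__(self):
        if self.nuclear_start > self.nuclear_end:
            raise ValueError("nuclear_start must be <= nuclear_end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class Numt:
    """A cluster of homology fragments treated as one mitonuclear insertion."""

    id: str
    scaffold: str
    fragments: list

    def __post_init__(self):
        if len({f.nuclear_scaffold for f in self.fragments}) != 1:
            raise ValueError("all fragments of a numt must share one scaffold")
        self.fragments = sorted(self.fragments, key=lambda f: f.nuclear_start)

    @property
    def span_start(self) -> int:
        return self.fragments[0].nuclear_start

    @property
    def span_end(self) -> int:
        return max(f.nuclear_end for f in self.fragments)

    @property
    def total_length(self) -> int:
        return sum(f.aligned_length for f in self.fragments)

    @property
    def mito_coordinate_list(self) -> list:
        return [(f.mito_start, f.mito_end) for f in self.fragments]

    @property
    def strand(self) -> str:
        strands = {f.strand for f in self.fragments}
        return strands.pop() if len(strands) == 1 else "."


@dataclass
class ConservationProfile:
    """Cross-genome presence summary for one numt (query-cover / identity)."""

    numt_id: str
    subject_genome_id: str
    query_cover: float
    top_hit_identity: float


def karlin_altschul_lambda(match: int, mismatch: int) -> float:
    """Solve (1/4) e^{lambda*match} + (3/4) e^{lambda*mismatch} = 1 (uniform bases)."""
    lo, hi = 1e-6, 10.0
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _extend_on_diagonal(scores: np.ndarray, seed_lo: int, seed_hi: int, xdrop: float):
    """Maximal-scoring X-drop extension of [seed_lo, seed_hi) along a diagonal.

    ``scores`` holds per-position match/mismatch scores along the diagonal;
    extension in each direction stops once the running score falls ``xdrop``
    below its maximum, and the segment is trimmed to the score argmax.
    """
    n = len(scores)
    # right extension
    hi = seed_hi
    best = cur = 0.0
    best_at = seed_hi
    i = seed_hi
    while i < n:
        cur += scores[i]
        if cur > best:
            best, best_at = cur, i + 1
        if best - cur > xdrop:
            break
        i += 1
    hi = best_at
    # left extension
    lo = seed_lo
    best = cur = 0.0
    best_at = seed_lo
    i = seed_lo - 1
    while i >= 0:
        cur += scores[i]
        if cur > best:
            best, best_at = cur, i
        if best - cur > xdrop:
            break
        i -= 1
    lo = best_at
    return lo, hi


def scan(
    mito: SeqRecord,
    nuclear,
    word_size: int = 20,
    e_cutoff: float = 0.01,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    xdrop: float = DEFAULT_XDROP,
) -> list:
    """Seed-and-extend homology search of ``mito`` against nuclear scaffolds.

    Respects the circular topology of the mitogenome by extending the query
    with its first ``word_size - 1`` bases; hits running across the origin
    are split at position 1 and reported as two mitochondrial intervals.
    Hits are returned sorted by bit score (best first).
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if isinstance(nuclear, SeqRecord):
        nuclear = [nuclear]
    if not nuclear:
        return []

    L = len(mito.seq)
    query = mito.seq + (mito.seq[: word_size - 1] if mito.circular else "")
    if len(query) < word_size:
        return []

    lam = karlin_altschul_lambda(match, mismatch)
    total_n = sum(len(s.seq) for s in nuclear)

    index: dict = {}
    for qpos in range(len(query) - word_size + 1):
        index.setdefault(query[qpos : qpos + word_size], []).append(qpos)

    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    hits = []
    for scaffold in nuclear:
        slen = len(scaffold.seq)
        for strand in "+-":
            subject = scaffold.seq if strand == "+" else reverse_complement(scaffold.seq)
            sarr = np.frombuffer(subject.encode(), dtype=np.uint8)
            diagonals: dict = {}
            for spos in range(slen - word_size + 1):
                for qpos in index.get(subject[spos : spos + word_size], ()):
                    diagonals.setdefault(spos - qpos, []).append(qpos)
            for diag, qseeds in diagonals.items():
                q0 = max(0, -diag)
                q1 = min(len(query), slen - diag)
                if q1 - q0 < word_size:
                    continue
                seg_q = qarr[q0:q1]
                seg_s = sarr[q0 + diag : q1 + diag]
                matches = seg_q == seg_s
                scores = np.where(matches, float(match), float(mismatch))
                qseeds = sorted(set(qseeds))
                covered_hi = -1
                for qs in qseeds:
                    a = qs - q0
                    if a + word_size <= covered_hi:
                        continue
                    lo, hi = _extend_on_diagonal(scores, a, a + word_size, xdrop)
                    covered_hi = hi
                    length = hi - lo
                    n_match = int(matches[lo:hi].sum())
                    raw = float(scores[lo:hi].sum())
                    bit = (lam * raw - math.log(KA_K)) / math.log(2.0)
                    evalue = len(query) * total_n * 2.0 ** (-bit)
                    if evalue > e_cutoff:
                        continue
                    qstart, qend = q0 + lo + 1, q0 + hi  # 1-based query coords
                    sstart, send = qstart + diag, qend + diag
                    pid = 100.0 * n_match / length
                    for q_a, q_b in _split_at_origin(qstart, qend, L, mito.circular):
                        frac = (q_b - q_a + 1) / length
                        hits.append(
                            _make_hit(
                                scaffold.id, slen, strand,
                                sstart + (q_a - qstart), sstart + (q_b - qstart),
                                ((q_a - 1) % L) + 1, ((q_b - 1) % L) + 1,
                                pid, q_b - q_a + 1,
                                bit * frac, evalue,
                            )
                        )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.bit_score, h.nuclear_scaffold, h.nuclear_start))
    return hits


def _split_at_origin(qstart: int, qend: int, L: int, circular: bool):
    if circular and qstart <= L < qend:
        return [(qstart, L), (L + 1, qend)]
    return [(qstart, qend)]


def _make_hit(scaffold_id, slen, strand, s_a, s_b, m_a, m_b, pid, length, bit, ev):
    if strand == "+":
        ns, ne = s_a, s_b
    else:
        # subject coordinates were on the reverse complement; map back
        ns, ne = slen - s_b + 1, slen - s_a + 1
    return HomologyHit(
        nuclear_scaffold=scaffold_id,
        nuclear_start=ns,
        nuclear_end=ne,
        strand=strand,
        mito_start=m_a,
        mito_end=m_b,
        percent_identity=pid,
        aligned_length=length,
        bit_score=bit,
        e_value=ev,
    )


def _dedupe(hits: list) -> list:
    """Drop hits whose nuclear interval is contained in a higher-scoring hit."""
    kept = []
    for h in sorted(hits, key=lambda h: -h.bit_score):
        contained = any(
            k.nuclear_scaffold == h.nuclear_scaffold
            and k.strand == h.strand
            and k.nuclear_start <= h.nuclear_start
            and h.nuclear_end <= k.nuclear_end
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


def filter_hits(hits, min_length: int = 200) -> list:
    """Keep hits strictly longer than ``min_length`` (the "> 200 bp" rule)."""
    return [h for h in hits if h.aligned_length > min_length]


def cluster_fragments(hits, max_gap: int = 10000) -> list:
    """Single-linkage clustering of fragments into numts per scaffold.

    Fragments whose nuclear intervals are separated by at most ``max_gap``
    intervening bases join one numt, irrespective of strand or mitochondrial
    origin.  Numts are numbered in genome order (scaffolds in natural sort
    order, then position); the result is invariant to input ordering.
    """
    by_scaffold: dict = {}
    for h in hits:
        by_scaffold.setdefault(h.nuclear_scaffold, []).append(h)

    numts = []
    counter = 0
    for scaffold in sorted(by_scaffold, key=_natural_key):
        frags = sorted(
            by_scaffold[scaffold], key=lambda h: (h.nuclear_start, h.nuclear_end)
        )
        cluster = [frags[0]]
        max_end = frags[0].nuclear_end
        for h in frags[1:]:
            gap = h.nuclear_start - max_end - 1
            if gap <= max_gap:
                cluster.append(h)
                max_end = max(max_end, h.nuclear_end)
            else:
                counter += 1
                numts.append(Numt(id=f"numt_{counter}", scaffold=scaffold, fragments=cluster))
                cluster = [h]
                max_end = h.nuclear_end
        counter += 1
        numts.append(Numt(id=f"numt_{counter}", scaffold=scaffold, fragments=cluster))
    return numts


def profile_conservation(
    numt_seq: SeqRecord,
    subject_genome,
    e_cutoff: float = 0.01,
    word_size: int = 20,
    subject_id: str | None = None,
) -> ConservationProfile:
    """Query-cover and top-hit identity of a numt against another genome.

    Query cover is the union of query positions covered by retained hits,
    as a percentage of the query length; the identity is that of the
    highest-scoring hit.  No hit at the cutoff gives (0, 0).
    """
    if isinstance(subject_genome, SeqRecord):
        subject_genome = [subject_genome]
    sid = subject_id or (subject_genome[0].id if subject_genome else "subject")
    query = SeqRecord(id=numt_seq.id, seq=numt_seq.seq, circular=False)
    hits = scan(query, subject_genome, word_size=word_size, e_cutoff=e_cutoff)
    if not hits:
        return ConservationProfile(numt_seq.id, sid, 0.0, 0.0)
    covered = np.zeros(len(query.seq) + 1, dtype=bool)
    for h in hits:
        covered[h.mito_start : h.mito_end + 1] = True
    cover = 100.0 * covered.sum() / len(query.seq)
    return ConservationProfile(numt_seq.id, sid, cover, hits[0].percent_identity)
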