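"""Edit-bounded location of attB queries (full site + two half sites).

Each attB contributes three queries: the full stored sequence, the left half
site (left flank + identity block) and the right half site (identity block +
right flank).  Queries are located on both strands of the target genome with
at most ``max_mismatch`` substitutions and ``max_gapcols`` gap columns over
the FULL query length (end gaps count as gap columns).

The matcher is exact under those bounds: candidate offsets come from a
pigeonhole seed scan (an alignment with at most e edit columns leaves at
least one of e+1 disjoint query chunks untouched), every candidate offset is
verified by banded evaluation of the three possible alignment spans, and
overlapping same-query alignments collapse to the single best-scoring one
per locus.  The result set equals what a brute-force per-offset scan returns
under the same bounds.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Mapping, Sequence

from iod._util import revcomp
from iod.registry import AttBRecord, SERINE

logger = logging.getLogger(__name__)

DEFAULT_SL = 16  # serine-family flank length
DEFAULT_YL = 10  # tyrosine-family flank length
MIN_QUERY_LEN = 16

FULL, LEFT, RIGHT = "full", "L", "R"


@dataclass
class QueryRecord:
    query_id: str
    sequence: str
    attb_ref: str
    part: str  # full | L | R
    flank_len: int


@dataclass
class MatchHit:
    query_id: str
    contig: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str  # + | -
    aln_len: int
    identities: int
    mismatches: int
    gap_columns: int
    identity_pct: float
    score: float
    attb_ref: str = ""
    part: str = FULL


def score_hit(hit: MatchHit) -> float:
    """Support score with BLASTN-like rewards/penalties (+2/-3, gap -5)."""
    return _score(hit.identities, hit.mismatches, hit.gap_columns)


def _score(identities: int, mismatches: int, gap_columns: int) -> float:
    return 2.0 * identities - 3.0 * mismatches - 5.0 * gap_columns


def build_query_set(
    attbs: Sequence[AttBRecord],
    sl: int = DEFAULT_SL,
    yl: int = DEFAULT_YL,
    min_query_len: int = MIN_QUERY_LEN,
) -> list[QueryRecord]:
    """Emit full/L/R queries per attB; flank length depends on family."""
    queries: list[QueryRecord] = []
    for attb in attbs:
        seq = attb.sequence.upper()
        ib_start, ib_end = attb.idblock_start, attb.idblock_end
        if not (1 <= ib_start <= ib_end <= len(seq)):
            raise ValueError(
                f"{attb.attb_id}: ID block {ib_start}..{ib_end} outside sequence of length {len(seq)}"
            )
        fl = sl if attb.family == SERINE else yl
        left_flank = seq[max(0, ib_start - 1 - fl) : ib_start - 1]
        right_flank = seq[ib_end : ib_end + fl]
        idblock = seq[ib_start - 1 : ib_end]
        if len(left_flank) < fl or len(right_flank) < fl:
            logger.warning(
                "%s: flanks truncated to available sequence (L=%d, R=%d, wanted %d)",
                attb.attb_id, len(left_flank), len(right_flank), fl,
            )
        for part, qseq in ((FULL, seq), (LEFT, left_flank + idblock), (RIGHT, idblock + right_flank)):
            if len(qseq) < min_query_len:
                logger.warning("%s|%s dropped: %d nt below query minimum %d",
                               attb.attb_id, part, len(qseq), min_query_len)
                continue
            queries.append(
                QueryRecord(
                    query_id=f"{attb.attb_id}|{part}",
                    sequence=qseq,
                    attb_ref=attb.attb_id,
                    part=part,
                    flank_len=fl,
                )
            )
    return queries


# ---------------------------------------------------------------------------
# alignment evaluation at one genome offset
# ---------------------------------------------------------------------------


def _best_alignment_at(q: str, genome: str, g: int, max_mm: int, max_gap: int):
    """Best admissible full-query alignment starting at 0-based offset *g*.

    Returns ``(span, mismatches, gap_columns, aln_len)`` or ``None``.  The
    three possible spans are L (ungapped), L-1 (one query base unaligned)
    and L+1 (one genome base unaligned); preference is by score, then fewer
    gap columns, then smaller span.
    """
    L = len(q)
    G = len(genome)
    candidates = []  # (score, -gaps, -span) best first

    if g + L <= G:
        w = genome[g : g + L]
        mm = sum(a != b for a, b in zip(q, w))
        if mm <= max_mm:
            candidates.append((_score(L - mm, mm, 0), 0, L, mm, L))

    if max_gap >= 1 and g + L - 1 <= G and L >= 2:
        w = genome[g : g + L - 1]
        # gap in the genome row: query base j unaligned
        suf = 0
        sufs = [0] * L  # sufs[j] = mismatches of q[j+1:] vs w[j:]
        for i in range(L - 2, -1, -1):
            suf += q[i + 1] != w[i]
            sufs[i] = suf
        pre = 0
        best_mm = sufs[0]
        for j in range(1, L):
            pre += q[j - 1] != w[j - 1]
            mm = pre + sufs[j]
            if mm < best_mm:
                best_mm = mm
        if best_mm <= max_mm:
            aln = L  # L-1 matched columns + 1 gap column
            candidates.append((_score(L - 1 - best_mm, best_mm, 1), 1, L - 1, best_mm, aln))

    if max_gap >= 1 and g + L + 1 <= G:
        w = genome[g : g + L + 1]
        # gap in the query row: genome base j unaligned
        sufs2 = [0] * (L + 1)  # sufs2[j] = mismatches of q[j:] vs w[j+1:]
        suf = 0
        for i in range(L - 1, -1, -1):
            suf += q[i] != w[i + 1]
            sufs2[i] = suf
        pre = 0
        best_mm = sufs2[0]
        for j in range(1, L + 1):
            pre += q[j - 1] != w[j - 1]
            mm = pre + sufs2[j]
            if mm < best_mm:
                best_mm = mm
        if best_mm <= max_mm:
            candidates.append((_score(L - best_mm, best_mm, 1), 1, L + 1, best_mm, L + 1))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    score, gaps, span, mm, aln = candidates[0]
    return span, mm, gaps, aln


def _seed_candidates(q: str, genome: str, n_chunks: int) -> set[int]:
    """Candidate alignment start offsets from exact occurrences of disjoint
    query chunks, each tried at diagonal shifts -1/0/+1."""
    L = len(q)
    m = max(1, L // n_chunks)
    cands: set[int] = set()
    hi = len(genome) - L + 1
    for c in range(n_chunks):
        off = c * m
        chunk = q[off : off + m]
        if not chunk:
            continue
        pos = genome.find(chunk)
        while pos != -1:
            for d in (-1, 0, 1):
                g = pos - off + d
                if 0 <= g <= hi:
                    cands.add(g)
            pos = genome.find(chunk, pos + 1)
    return cands


def _scan_one_strand(
    query: QueryRecord, qseq: str, contig: str, genome: str, strand: str,
    max_mm: int, max_gap: int,
) -> list[MatchHit]:
    L = len(qseq)
    if L > len(genome) + max_gap:
        return []
    e = max_mm + max_gap
    raw = []
    for g in sorted(_seed_candidates(qseq, genome, e + 1)):
        found = _best_alignment_at(qseq, genome, g, max_mm, max_gap)
        if found is None:
            continue
        span, mm, gaps, aln = found
        ident = aln - mm - gaps
        raw.append(
            MatchHit(
                query_id=query.query_id,
                contig=contig,
                start=g + 1,
                end=g + span,
                strand=strand,
                aln_len=aln,
                identities=ident,
                mismatches=mm,
                gap_columns=gaps,
                identity_pct=100.0 * ident / aln,
                score=_score(ident, mm, gaps),
                attb_ref=query.attb_ref,
                part=query.part,
            )
        )
    return _suppress_shadows(raw)


def _suppress_shadows(hits: list[MatchHit]) -> list[MatchHit]:
    """Collapse overlapping same-query alignments to the best one per locus.

    A 1-gap alignment one offset away from an exact hit is admissible under
    the bounds but is a shadow of the same locus, not an extra occurrence.
    """
    if len(hits) <= 1:
        return hits
    hits.sort(key=lambda h: h.start)
    out: list[MatchHit] = []
    cluster: list[MatchHit] = []
    cluster_end = -1
    for h in hits:
        if cluster and h.start > cluster_end:
            out.append(_cluster_best(cluster))
            cluster = []
            cluster_end = -1
        cluster.append(h)
        cluster_end = max(cluster_end, h.end)
    if cluster:
        out.append(_cluster_best(cluster))
    return out


def _cluster_best(cluster: list[MatchHit]) -> MatchHit:
    return min(cluster, key=lambda h: (-h.score, h.gap_columns, h.start, h.end))


def _scan_query(
    query: QueryRecord, genome: Mapping[str, str], max_mm: int, max_gap: int
) -> list[MatchHit]:
    hits: list[MatchHit] = []
    rc = revcomp(query.sequence)
    for contig, seq in genome.items():
        hits.extend(_scan_one_strand(query, query.sequence, contig, seq, "+", max_mm, max_gap))
        hits.extend(_scan_one_strand(query, rc, contig, seq, "-", max_mm, max_gap))
    return hits


def find_hits(
    queries: Sequence[QueryRecord],
    genome: Mapping[str, str],
    max_mismatch: int = 2,
    max_gapcols: int = 1,
    threads: int = 1,
) -> list[MatchHit]:
    """Locate every edit-bounded occurrence of each query in *genome*.

    Output order is normalized to (contig, start, query_id, strand) so it is
    independent of thread count.
    """
    genome = {name: seq.upper() for name, seq in genome.items()}
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            chunks = pool.map(lambda q: _scan_query(q, genome, max_mismatch, max_gapcols), queries)
            hits = [h for chunk in chunks for h in chunk]
    else:
        hits = [h for q in queries for h in _scan_query(q, genome, max_mismatch, max_gapcols)]
    hits.sort(key=lambda h: (h.contig, h.start, h.query_id, h.strand))
    return hits


def hits_to_tsv(hits: Sequence[MatchHit], path) -> None:
    """Debug dump mirroring tabular BLAST column naming."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "strand", "bitscore"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.contig, f"{h.identity_pct:.2f}", str(h.aln_len),
                        str(h.mismatches), str(h.gap_columns), "1",
                        str(h.aln_len - h.gap_columns), str(h.start), str(h.end),
                        h.strand, f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )
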