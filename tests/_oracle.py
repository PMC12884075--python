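"""Independent brute-force matcher oracle.

Evaluates every genome offset exhaustively with vectorized diagonal
mismatch-cumsum arithmetic (no seeding, no shared code with the package
matcher) and applies the same canonical per-offset alignment choice and
overlap suppression so result sets are directly comparable.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def _span_L(Q: np.ndarray, S: np.ndarray) -> np.ndarray:
    """mm[g] for ungapped alignment at each offset; len G-L+1."""
    L = Q.size
    W = np.lib.stride_tricks.sliding_window_view(S, L)
    return (W != Q).sum(axis=1)


def _span_del(Q: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Best mm[g] over deletion position (one query base unaligned); windows L-1."""
    L = Q.size
    W = np.lib.stride_tricks.sliding_window_view(S, L - 1)
    A = (W != Q[: L - 1]).astype(np.int32)  # q[i] vs w[i]
    B = (W != Q[1:]).astype(np.int32)  # q[i+1] vs w[i]
    n = W.shape[0]
    pre = np.zeros((n, L), dtype=np.int32)
    pre[:, 1:] = np.cumsum(A, axis=1)
    suf = np.zeros((n, L), dtype=np.int32)
    suf[:, : L - 1] = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    return (pre + suf).min(axis=1)


def _span_ins(Q: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Best mm[g] over insertion position (one genome base unaligned); windows L+1."""
    L = Q.size
    W = np.lib.stride_tricks.sliding_window_view(S, L + 1)
    A = (W[:, :L] != Q).astype(np.int32)  # q[i] vs w[i]
    B = (W[:, 1:] != Q).astype(np.int32)  # q[i] vs w[i+1]
    n = W.shape[0]
    pre = np.zeros((n, L + 1), dtype=np.int32)
    pre[:, 1:] = np.cumsum(A, axis=1)
    suf = np.zeros((n, L + 1), dtype=np.int32)
    suf[:, :L] = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    return (pre + suf).min(axis=1)


def _score(ident: int, mm: int, gaps: int) -> float:
    return 2.0 * ident - 3.0 * mm - 5.0 * gaps


def _strand_hits(q: str, seq: str, max_mm: int, max_gap: int):
    """Per-offset best admissible alignments: list of (start0, span, mm, gaps)."""
    Q = np.frombuffer(q.encode(), dtype=np.uint8)
    S = np.frombuffer(seq.encode(), dtype=np.uint8)
    L, G = Q.size, S.size
    options: dict[int, list] = {}

    def add(g, span, mm, gaps, aln):
        sc = _score(aln - mm - gaps, mm, gaps)
        options.setdefault(g, []).append((-sc, gaps, span, mm, aln))

    if G >= L:
        for g, mm in enumerate(_span_L(Q, S)):
            if mm <= max_mm:
                add(g, L, int(mm), 0, L)
    if max_gap >= 1 and L >= 2 and G >= L - 1:
        for g, mm in enumerate(_span_del(Q, S)):
            if mm <= max_mm:
                add(g, L - 1, int(mm), 1, L)
    if max_gap >= 1 and G >= L + 1:
        for g, mm in enumerate(_span_ins(Q, S)):
            if mm <= max_mm:
                add(g, L + 1, int(mm), 1, L + 1)

    per_offset = []
    for g in sorted(options):
        neg_sc, gaps, span, mm, aln = sorted(options[g])[0]
        per_offset.append((g, span, mm, gaps, -neg_sc))

    # suppress shadows: overlapping alignments collapse to the best one
    out = []
    cluster: list = []
    cluster_end = -1
    for item in per_offset:
        g, span = item[0], item[1]
        if cluster and g > cluster_end:
            out.append(_pick(cluster))
            cluster = []
            cluster_end = -1
        cluster.append(item)
        cluster_end = max(cluster_end, g + span - 1)
    if cluster:
        out.append(_pick(cluster))
    return out


def _pick(cluster):
    # (g, span, mm, gaps, score): best score, then fewest gaps, then leftmost
    return min(cluster, key=lambda t: (-t[4], t[3], t[0], t[0] + t[1] - 1))


def oracle_find(query: str, genome: dict[str, str], max_mm: int = 2, max_gap: int = 1):
    """Set of (contig, start1, end1, strand, mismatches, gap_columns)."""
    hits = set()
    for contig, seq in genome.items():
        seq = seq.upper()
        for strand, q in (("+", query.upper()), ("-", rc(query.upper()))):
            for g, span, mm, gaps, _sc in _strand_hits(q, seq, max_mm, max_gap):
                hits.add((contig, g + 1, g + span, strand, mm, gaps))
    return hits
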