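"""Hit filtering, occupancy inference, refinement and candidate ranking.

Surviving hits for one attB either describe a single coherent locus (a
candidate landing pad) or several loci — the signature of a genomic island
sitting between the two half sites, which is tested against the lengths of
the reference GIs known to use that attB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from iod._util import homopolymer_run, revcomp
from iod.match import FULL, LEFT, RIGHT, MatchHit
from iod.registry import AttBRecord, ReferenceDB

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MAX_GAPCOLS = 1
DEFAULT_ND_THRESHOLD = 0.05
DEFAULT_HOMOPOLYMER_MIN = 10


@dataclass
class OccupancyEvidence:
    attb_ref: str
    left_hit: MatchHit
    right_hit: MatchHit
    expected: int
    actual: int
    normalized_difference: float
    gi_ref: str
    cross_contig: bool


@dataclass
class SiteCall:
    attb_ref: str
    contig: str
    start: int
    end: int
    strand: str
    status: str  # candidate | occupied | questionable | duplicate
    reason: str  # ok | in_occupied | multi_idblock | homopolymer_idblock | overlap_loser | multi_hit
    best_hit_score: float
    ref_gi: str
    ref_gi_support: float
    rank: int = 0


@dataclass
class ClassifyResult:
    ranked: list[SiteCall]
    duplicates: list[SiteCall]
    questionable: list[SiteCall]
    occupied: list[SiteCall]
    evidence: dict[str, OccupancyEvidence]
    rejected_hits: list[MatchHit]


def normalized_difference(expected: float, actual: float) -> float:
    return (expected - actual) / (expected + actual)


# ---------------------------------------------------------------------------
# hit filtering (rules i-iv)
# ---------------------------------------------------------------------------


def _overlap_clusters(hits: Sequence[MatchHit]) -> list[list[MatchHit]]:
    """Single-linkage clusters of interval-overlapping hits per contig."""
    clusters: list[list[MatchHit]] = []
    for h in sorted(hits, key=lambda x: (x.contig, x.start, x.end)):
        if (
            clusters
            and clusters[-1][0].contig == h.contig
            and h.start <= max(x.end for x in clusters[-1])
        ):
            clusters[-1].append(h)
        else:
            clusters.append([h])
    return clusters


def filter_hits(
    hits: Sequence[MatchHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_gapcols: int = DEFAULT_MAX_GAPCOLS,
) -> tuple[list[MatchHit], list[MatchHit], list[MatchHit]]:
    """Split hits into (kept, occupancy_pool, rejected).

    Per-hit rules: identity below *min_identity* percent, more than
    *max_gapcols* gap columns, or more than *max_mismatch* mismatches reject
    the hit outright.  Then, per attB, hits at two or more distinct loci go
    to the occupancy pool; a single coherent locus that includes a full-site
    hit is kept.  A full hit with its own half hits nested at the same locus
    counts as one locus.
    """
    rejected: list[MatchHit] = []
    surviving: dict[str, list[MatchHit]] = {}
    for h in hits:
        if h.identity_pct < min_identity or h.gap_columns > max_gapcols or h.mismatches > max_mismatch:
            rejected.append(h)
        else:
            surviving.setdefault(h.attb_ref, []).append(h)

    kept: list[MatchHit] = []
    pool: list[MatchHit] = []
    for attb_ref in sorted(surviving):
        group = surviving[attb_ref]
        clusters = _overlap_clusters(group)
        if len(clusters) == 1 and any(h.part == FULL for h in clusters[0]):
            kept.extend(group)
        else:
            pool.extend(group)
    return kept, pool, rejected


# ---------------------------------------------------------------------------
# occupancy inference
# ---------------------------------------------------------------------------


def _pair_actual(
    l: MatchHit, r: MatchHit, contig_lengths: Mapping[str, int], span_mode: str
) -> tuple[int, bool] | None:
    """Observed separation of an L/R half-site pair, or None if incompatible."""
    if l.contig == r.contig:
        if l.strand != r.strand:
            return None
        if l.strand == "+":
            if l.start > r.start:
                return None
            outer = r.end - l.start + 1
            inner = r.start - l.end - 1
        else:
            if r.start > l.start:
                return None
            outer = l.end - r.start + 1
            inner = l.start - r.end - 1
        actual = outer if span_mode == "outer" else inner
        return (actual, False) if actual >= 0 else None
    # different contigs: hit orientation decides which terminus the island
    # would run through
    dist_l = contig_lengths[l.contig] - l.start + 1 if l.strand == "+" else l.end
    dist_r = r.end if r.strand == "+" else contig_lengths[r.contig] - r.start + 1
    return dist_l + dist_r, True


def infer_occupancy(
    pool: Sequence[MatchHit],
    db: ReferenceDB,
    contig_lengths: Mapping[str, int],
    nd_threshold: float = DEFAULT_ND_THRESHOLD,
    span_mode: str = "outer",
) -> dict[str, OccupancyEvidence]:
    """Best occupancy evidence per attB from L/R half-site pairs.

    Each candidate reference-GI length ("expected") is tested against each
    observed pair separation ("actual"); the pair/GI combination minimizing
    the absolute normalized difference wins, provided it clears
    *nd_threshold*.
    """
    attbs_by_id = {a.attb_id: a for a in db.attbs}
    grouped: dict[str, list[MatchHit]] = {}
    for h in pool:
        grouped.setdefault(h.attb_ref, []).append(h)

    evidence: dict[str, OccupancyEvidence] = {}
    for attb_ref in sorted(grouped):
        attb = attbs_by_id.get(attb_ref)
        gi_lengths = []
        if attb is not None:
            gi_lengths = [
                (db.gis[g].length, g) for g in attb.gi_refs if g in db.gis
            ]
        if not gi_lengths:
            logger.warning("occupancy: attB %s has no reference GI length; skipped", attb_ref)
            continue
        lefts = [h for h in grouped[attb_ref] if h.part == LEFT]
        rights = [h for h in grouped[attb_ref] if h.part == RIGHT]
        best: OccupancyEvidence | None = None
        for l in lefts:
            for r in rights:
                pa = _pair_actual(l, r, contig_lengths, span_mode)
                if pa is None:
                    continue
                actual, cross = pa
                for expected, gi_id in sorted(gi_lengths, key=lambda x: (x[0], x[1])):
                    nd = normalized_difference(expected, actual)
                    if abs(nd) >= nd_threshold:
                        continue
                    if best is None or abs(nd) < abs(best.normalized_difference):
                        best = OccupancyEvidence(
                            attb_ref=attb_ref,
                            left_hit=l,
                            right_hit=r,
                            expected=expected,
                            actual=actual,
                            normalized_difference=nd,
                            gi_ref=gi_id,
                            cross_contig=cross,
                        )
        if best is not None:
            evidence[attb_ref] = best
    return evidence


# ---------------------------------------------------------------------------
# refining filters
# ---------------------------------------------------------------------------


def _count_idblock_loci(idblock: str, genome: Mapping[str, str]) -> int:
    """Distinct exact-match loci of the ID block, either strand."""
    loci: set[tuple[str, int]] = set()
    rc = revcomp(idblock)
    for contig, seq in genome.items():
        for probe in {idblock, rc}:
            pos = seq.find(probe)
            while pos != -1:
                loci.add((contig, pos))
                pos = seq.find(probe, pos + 1)
    return len(loci)


def refine(
    candidates: Sequence[SiteCall],
    occupied: Sequence[SiteCall],
    genome: Mapping[str, str],
    attbs_by_id: Mapping[str, AttBRecord],
    homopolymer_min: int = DEFAULT_HOMOPOLYMER_MIN,
) -> tuple[list[SiteCall], list[SiteCall]]:
    """Demote questionable candidates; returns (final_pool, questionable)."""
    occ_by_contig: dict[str, list[SiteCall]] = {}
    for o in occupied:
        occ_by_contig.setdefault(o.contig, []).append(o)

    final_pool: list[SiteCall] = []
    questionable: list[SiteCall] = []
    for c in candidates:
        overlapping = any(
            c.start <= o.end and o.start <= c.end for o in occ_by_contig.get(c.contig, [])
        )
        if overlapping:
            c.status, c.reason = "questionable", "in_occupied"
            questionable.append(c)
            continue
        idblock = attbs_by_id[c.attb_ref].idblock_seq
        # homopolymer first: a long run matches itself at overlapping offsets
        # and would otherwise always be diagnosed as a multi-copy ID block
        if homopolymer_run(idblock) >= homopolymer_min:
            c.status, c.reason = "questionable", "homopolymer_idblock"
            questionable.append(c)
            continue
        if _count_idblock_loci(idblock, genome) > 1:
            c.status, c.reason = "questionable", "multi_idblock"
            questionable.append(c)
            continue
        final_pool.append(c)
    return final_pool, questionable


# ---------------------------------------------------------------------------
# binning and ranking
# ---------------------------------------------------------------------------


def _call_clusters(calls: Sequence[SiteCall]) -> list[list[SiteCall]]:
    clusters: list[list[SiteCall]] = []
    for c in sorted(calls, key=lambda x: (x.contig, x.start, x.end, x.attb_ref)):
        if (
            clusters
            and clusters[-1][0].contig == c.contig
            and c.start <= max(x.end for x in clusters[-1])
        ):
            clusters[-1].append(c)
        else:
            clusters.append([c])
    return clusters


def bin_and_select(final_pool: Sequence[SiteCall]) -> tuple[list[SiteCall], list[SiteCall]]:
    """Pick one winner per overlap bin; rank winners by reference-GI support."""
    winners: list[SiteCall] = []
    duplicates: list[SiteCall] = []
    for cluster in _call_clusters(final_pool):
        best = min(
            cluster,
            key=lambda c: (-c.best_hit_score, -c.ref_gi_support, c.start, c.attb_ref),
        )
        winners.append(best)
        for c in cluster:
            if c is not best:
                c.status, c.reason = "duplicate", "overlap_loser"
                duplicates.append(c)
    winners.sort(key=lambda c: (-c.ref_gi_support, -c.best_hit_score, c.contig, c.start, c.attb_ref))
    for i, w in enumerate(winners, start=1):
        w.rank = i
        w.status, w.reason = "candidate", "ok"
    return winners, duplicates


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _best_ref_gi(attb: AttBRecord, db: ReferenceDB) -> tuple[str, float]:
    """Highest-support reference GI of an attB (ties break on gi_id)."""
    best: tuple[tuple[float, str], str, float] | None = None
    for gi_id in attb.gi_refs:
        gi = db.gis.get(gi_id)
        if gi is None:
            continue
        key = (-gi.support_score, gi_id)
        if best is None or key < best[0]:
            best = (key, gi_id, gi.support_score)
    return ("", 0.0) if best is None else (best[1], best[2])


def classify_hits(
    hits: Sequence[MatchHit],
    db: ReferenceDB,
    genome: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_gapcols: int = DEFAULT_MAX_GAPCOLS,
    nd_threshold: float = DEFAULT_ND_THRESHOLD,
    homopolymer_min: int = DEFAULT_HOMOPOLYMER_MIN,
    span_mode: str = "outer",
) -> ClassifyResult:
    """Run the full classification stage on matcher output."""
    genome = {k: v.upper() for k, v in genome.items()}
    contig_lengths = {k: len(v) for k, v in genome.items()}
    attbs_by_id = {a.attb_id: a for a in db.attbs}

    kept, pool, rejected = filter_hits(hits, min_identity, max_mismatch, max_gapcols)
    logger.info("filter_hits: kept=%d pool=%d rejected=%d", len(kept), len(pool), len(rejected))

    # candidate calls from kept loci
    candidates: list[SiteCall] = []
    kept_by_attb: dict[str, list[MatchHit]] = {}
    for h in kept:
        kept_by_attb.setdefault(h.attb_ref, []).append(h)
    for attb_ref in sorted(kept_by_attb):
        group = kept_by_attb[attb_ref]
        full = max((h for h in group if h.part == FULL), key=lambda h: h.score)
        gi_id, support = _best_ref_gi(attbs_by_id[attb_ref], db)
        candidates.append(
            SiteCall(
                attb_ref=attb_ref,
                contig=full.contig,
                start=full.start,
                end=full.end,
                strand=full.strand,
                status="candidate",
                reason="ok",
                best_hit_score=max(h.score for h in group),
                ref_gi=gi_id,
                ref_gi_support=support,
            )
        )

    # occupied calls (and pool attBs that fail the length test)
    evidence = infer_occupancy(pool, db, contig_lengths, nd_threshold, span_mode)
    occupied_calls: list[SiteCall] = []
    questionable: list[SiteCall] = []
    pool_by_attb: dict[str, list[MatchHit]] = {}
    for h in pool:
        pool_by_attb.setdefault(h.attb_ref, []).append(h)
    for attb_ref in sorted(pool_by_attb):
        group = pool_by_attb[attb_ref]
        ev = evidence.get(attb_ref)
        if ev is not None:
            l, r = ev.left_hit, ev.right_hit
            if ev.cross_contig:
                # only the left-hit interval is locatable on one contig
                contig, start, end = l.contig, l.start, l.end
            else:
                contig = l.contig
                start, end = min(l.start, r.start), max(l.end, r.end)
            occupied_calls.append(
                SiteCall(
                    attb_ref=attb_ref,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=l.strand,
                    status="occupied",
                    reason="ok",
                    best_hit_score=max(h.score for h in group),
                    ref_gi=ev.gi_ref,
                    ref_gi_support=db.gis[ev.gi_ref].support_score if ev.gi_ref in db.gis else 0.0,
                )
            )
        else:
            best = max(group, key=lambda h: (h.score, -h.start))
            gi_id, support = (
                _best_ref_gi(attbs_by_id[attb_ref], db) if attb_ref in attbs_by_id else ("", 0.0)
            )
            questionable.append(
                SiteCall(
                    attb_ref=attb_ref,
                    contig=best.contig,
                    start=best.start,
                    end=best.end,
                    strand=best.strand,
                    status="questionable",
                    reason="multi_hit",
                    best_hit_score=best.score,
                    ref_gi=gi_id,
                    ref_gi_support=support,
                )
            )

    # occupied sites deduplicated by overlapping coordinates
    duplicates: list[SiteCall] = []
    occupied_final: list[SiteCall] = []
    for cluster in _call_clusters(occupied_calls):
        best = min(
            cluster,
            key=lambda c: (abs(evidence[c.attb_ref].normalized_difference), c.attb_ref),
        )
        occupied_final.append(best)
        for c in cluster:
            if c is not best:
                c.status, c.reason = "duplicate", "overlap_loser"
                duplicates.append(c)

    final_pool, more_questionable = refine(
        candidates, occupied_final, genome, attbs_by_id, homopolymer_min
    )
    questionable.extend(more_questionable)

    ranked, dup_losers = bin_and_select(final_pool)
    duplicates.extend(dup_losers)

    logger.info(
        "classify: candidates=%d duplicates=%d questionable=%d occupied=%d",
        len(ranked), len(duplicates), len(questionable), len(occupied_final),
    )
    return ClassifyResult(
        ranked=ranked,
        duplicates=duplicates,
        questionable=questionable,
        occupied=occupied_final,
        evidence=evidence,
        rejected_hits=rejected,
    )
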