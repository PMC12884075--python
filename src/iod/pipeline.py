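"""End-to-end run modes: taxonomic (neighbor-driven query set) and search."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

from iod._util import read_fasta
from iod.classify import classify_hits
from iod.match import build_query_set, find_hits
from iod.registry import AttBRecord, ReferenceDB, load_db
from iod.reports import DiscoveryRateModel, RunConfig, discovery_rate, write_reports
from iod.sketch import collect_attbs, load_sketches, rank_neighbors, sketch_genome

logger = logging.getLogger(__name__)


def _require(path: str, what: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise FileNotFoundError(f"{what} not found: {path!r}")
    return p


def _run_common(
    config: RunConfig,
    genome: dict[str, str],
    db: ReferenceDB,
    queried: Sequence[AttBRecord],
) -> dict[str, Path]:
    discovery_rate(
        DiscoveryRateModel(
            genome_length=sum(len(s) for s in genome.values()),
            kmer_length=config.min_attb_len,
            n_queries=len(queried),
        )
    )
    queries = build_query_set(queried, sl=config.sl, yl=config.yl)
    logger.info("query set: %d attBs -> %d queries", len(queried), len(queries))
    hits = find_hits(
        queries,
        genome,
        max_mismatch=config.max_mismatch,
        max_gapcols=config.max_gapcols,
        threads=config.threads,
    )
    logger.info("matcher: %d raw hits", len(hits))
    result = classify_hits(
        hits,
        db,
        genome,
        min_identity=config.min_identity,
        max_mismatch=config.max_mismatch,
        max_gapcols=config.max_gapcols,
        nd_threshold=config.nd_threshold,
        homopolymer_min=config.homopolymer_min,
    )
    return write_reports(
        result.ranked,
        result.duplicates,
        result.questionable,
        result.occupied,
        config.out,
        db=db,
        evidence=result.evidence,
        queried_attbs=list(queried),
    )


def run_search(config: RunConfig, query_attbs: Sequence[AttBRecord] | None = None) -> dict[str, Path]:
    """Query a caller-supplied attB list (or the whole DB) against the genome."""
    genome = read_fasta(_require(config.genome, "genome FASTA"))
    db = load_db(_require(config.db, "reference DB"))
    if query_attbs is not None:
        queried = list(query_attbs)
    elif config.attb_list:
        wanted = {
            line.strip()
            for line in open(_require(config.attb_list, "attB list"))
            if line.strip()
        }
        queried = [a for a in db.attbs if a.attb_id in wanted]
        missing = wanted - {a.attb_id for a in queried}
        if missing:
            logger.warning("attB ids not in DB: %s", ", ".join(sorted(missing)))
    else:
        queried = list(db.attbs)
    if not queried:
        logger.warning("empty query set; reports will contain headers only")
    return _run_common(config, genome, db, queried)


def run_taxonomic(config: RunConfig) -> dict[str, Path]:
    """Sketch the target, rank reference genomes, collect nearby attBs, search."""
    genome = read_fasta(_require(config.genome, "genome FASTA"))
    db = load_db(_require(config.db, "reference DB"))
    refs = load_sketches(_require(config.sketches, "sketch cache"))
    target = sketch_genome(
        list(genome.values()), genome_id="target",
        k=config.sketch_k, s=config.sketch_s, seed=config.seed,
    )
    ranked = rank_neighbors(target, refs, taxonomy=db.taxonomy)
    logger.info("nearest reference genome: %s (d=%.4f)", ranked[0].genome_id, ranked[0].distance)
    queried = collect_attbs(ranked, db, n_min=config.n_min)
    logger.info("taxonomic query set: %d attBs (n_min=%d)", len(queried), config.n_min)
    if not queried:
        logger.warning("no attBs collected from taxonomic neighbors")
    return _run_common(config, genome, db, queried)
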