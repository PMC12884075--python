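"""Run configuration, the four standard report files and the discovery-rate model."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from iod._util import sig3
from iod.classify import OccupancyEvidence, SiteCall
from iod.registry import AttBRecord, ReferenceDB

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; round-trips losslessly through YAML."""

    mode: str = "taxonomic"  # taxonomic | search
    genome: str = ""
    db: str = ""
    sketches: str = ""
    out: str = "iod_out"
    attb_list: str = ""
    n_min: int = 500
    sl: int = 16
    yl: int = 10
    threads: int = 1
    min_attb_len: int = 22
    homopolymer_min: int = 10
    nd_threshold: float = 0.05
    min_identity: float = 95.0
    max_mismatch: int = 2
    max_gapcols: int = 1
    sketch_k: int = 21
    sketch_s: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_min", "sl", "yl", "threads", "min_attb_len", "homopolymer_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nd_threshold <= 0:
            raise ValueError("nd_threshold must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class DiscoveryRateModel:
    """Chance of a random k-mer occurring in a genome of length L."""

    genome_length: int
    kmer_length: int
    n_queries: int
    per_kmer_rate: float | None = None  # override; computed from L and k if None


def discovery_rate(model: DiscoveryRateModel) -> tuple[float, float]:
    """Per-k-mer rate p = 2 L / 4^k and the linear any-of-n rate n*p."""
    p = model.per_kmer_rate
    if p is None:
        p = 2.0 * model.genome_length * 4.0 ** (-model.kmer_length)
    p_any = model.n_queries * p
    logger.info(
        "discovery rate: p=%.3g per %d-mer, any-of-%d=%.3g",
        sig3(p), model.kmer_length, model.n_queries, sig3(p_any),
    )
    return p, p_any


# ---------------------------------------------------------------------------
# report files
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "rank", "attb_id", "contig", "start", "end", "strand", "attb_seq",
    "idblock_seq", "family", "best_hit_score", "ref_gi_id", "ref_gi_support",
    "integrase_ids", "all_refs",
]
OCCUPIED_COLUMNS = [
    "contig", "start", "end", "attb_id", "gi_ref", "expected", "actual",
    "normalized_difference", "cross_contig",
]


def _all_refs(attb: AttBRecord, db: ReferenceDB) -> str:
    if len(attb.gi_refs) <= 1:
        return ""
    parts = []
    for gi_id in attb.gi_refs:
        gi = db.gis.get(gi_id)
        ints = ",".join(gi.integrase_ids) if gi else ""
        parts.append(f"{gi_id}|{ints}")
    return ";".join(parts)


def _candidate_row(call: SiteCall, db: ReferenceDB, attbs: Mapping[str, AttBRecord]) -> list[str]:
    attb = attbs[call.attb_ref]
    return [
        str(call.rank) if call.rank else "",
        attb.attb_id,
        call.contig,
        str(call.start),
        str(call.end),
        call.strand,
        attb.sequence,
        attb.idblock_seq,
        attb.family,
        f"{call.best_hit_score:g}",
        call.ref_gi,
        f"{call.ref_gi_support:g}",
        ",".join(attb.integrase_refs),
        _all_refs(attb, db),
    ]


def write_reports(
    ranked: Sequence[SiteCall],
    duplicates: Sequence[SiteCall],
    questionable: Sequence[SiteCall],
    occupied: Sequence[SiteCall],
    outdir: str | Path,
    *,
    db: ReferenceDB,
    evidence: Mapping[str, OccupancyEvidence],
    queried_attbs: Sequence[AttBRecord],
) -> dict[str, Path]:
    """Write final_candidates.tsv, attb_dupes.tsv, occupied.tsv and isles.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attbs = {a.attb_id: a for a in queried_attbs}
    for a in db.attbs:  # calls may reference DB attBs outside the query set
        attbs.setdefault(a.attb_id, a)

    paths = {
        "final_candidates": outdir / "final_candidates.tsv",
        "attb_dupes": outdir / "attb_dupes.tsv",
        "occupied": outdir / "occupied.tsv",
        "isles": outdir / "isles.json",
    }

    with open(paths["final_candidates"], "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for call in ranked:
            fh.write("\t".join(_candidate_row(call, db, attbs)) + "\n")

    with open(paths["attb_dupes"], "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS + ["reason"]) + "\n")
        for call in sorted(
            list(duplicates) + list(questionable),
            key=lambda c: (c.contig, c.start, c.attb_ref),
        ):
            fh.write("\t".join(_candidate_row(call, db, attbs) + [call.reason]) + "\n")

    with open(paths["occupied"], "w") as fh:
        fh.write("\t".join(OCCUPIED_COLUMNS) + "\n")
        for call in sorted(occupied, key=lambda c: (c.contig, c.start, c.attb_ref)):
            ev = evidence[call.attb_ref]
            fh.write(
                "\t".join(
                    [
                        call.contig,
                        str(call.start),
                        str(call.end),
                        call.attb_ref,
                        ev.gi_ref,
                        str(ev.expected),
                        str(ev.actual),
                        f"{ev.normalized_difference:.6f}",
                        str(ev.cross_contig),
                    ]
                )
                + "\n"
            )

    isles = {
        a.attb_id: [dataclasses.asdict(db.gis[g]) for g in a.gi_refs if g in db.gis]
        for a in sorted(queried_attbs, key=lambda x: x.attb_id)
    }
    with open(paths["isles"], "w") as fh:
        json.dump(isles, fh, indent=1, sort_keys=True)

    logger.info(
        "reports: %d candidates, %d dupes/questionable, %d occupied, %d attBs in isles.json",
        len(ranked), len(duplicates) + len(questionable), len(occupied), len(isles),
    )
    return paths
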