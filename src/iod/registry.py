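"""Reference database construction: integrase integrity filters and attB dedup.

The reference collection pairs attachment sites (attB) extracted from
predicted genomic islands (GIs) with the integrase proteins encoded on those
islands.  Before an attB is queryable, its cognate integrases must pass
family-specific integrity rules; attB sequences are then deduplicated so a
single record carries the union of supporting GIs and integrases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SearchIO

from iod._util import iter_tsv, read_fasta, write_fasta

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Default tyrosine-recombinase HMM panel.  The panel is configuration, not
#: a built-in resource: callers supply the names present in their domtblout.
DEFAULT_TYROSINE_PANEL = frozenset(
    {
        "Y-Int",
        "Phage_integrase",
        "Arm-DNA-bind",
        "Xer",
        "Integron",
    }
)
DEFAULT_EXCLUDED = frozenset({"Xer", "Integron"})

#: HMM names that mark the serine-recombinase domain architecture.
RESOLVASE = "Resolvase"
RECOMBINASE = "Recombinase"
S_CORE_IS607 = "S-Core_IS607"
SERINE_HMMS = frozenset({RESOLVASE, RECOMBINASE, S_CORE_IS607})

# family / verdict enums are plain strings for painless JSON round-trips
TYROSINE = "tyrosine"
SERINE = "serine"


class ReferenceError(ValueError):
    """Raised on dangling references or malformed reference inputs."""


@dataclass
class GIRecord:
    """One predicted genomic island with its attB and integrase links."""

    gi_id: str
    contig_accession: str
    start: int
    end: int
    length: int
    support_score: float
    attb_seq: str
    idblock_start: int
    idblock_end: int
    target_class: str
    integrase_ids: list[str]

    def __post_init__(self) -> None:
        if not (1 <= self.idblock_start <= self.idblock_end <= len(self.attb_seq)):
            raise ReferenceError(
                f"GI {self.gi_id}: ID-block coordinates "
                f"{self.idblock_start}..{self.idblock_end} outside attB of "
                f"length {len(self.attb_seq)}"
            )
        if self.length <= 0:
            raise ReferenceError(f"GI {self.gi_id}: non-positive length {self.length}")
        if not self.integrase_ids:
            raise ReferenceError(f"GI {self.gi_id}: no integrase ids")

    @property
    def genome_accession(self) -> str:
        """Genome accession encoded as the leading ``|``-separated token."""
        return self.gi_id.split("|", 1)[0]


@dataclass
class DomainHit:
    """A single profile-HMM domain hit on a protein (hmmsearch orientation)."""

    protein_id: str
    hmm_name: str
    hmm_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    score: float
    delta_h: int | None = None
    delta_a: int | None = None
    ddha: int | None = None


@dataclass
class IntegraseRecord:
    protein_id: str
    sequence: str
    family: str  # tyrosine | serine
    length_aa: int
    best_hit: DomainHit | None = None
    serine_class: str = "none"  # resolvase_recombinase | s_core_is607 | none
    verdict: str = "pass"
    reject_reason: str = "none"  # no_hmm | xer_or_integron | too_long | truncated | bad_architecture | none


@dataclass
class AttBRecord:
    """A deduplicated attachment-site sequence and its provenance."""

    attb_id: str
    sequence: str
    idblock_start: int
    idblock_end: int
    family: str
    gi_refs: list[str] = field(default_factory=list)
    integrase_refs: list[str] = field(default_factory=list)

    @property
    def idblock_seq(self) -> str:
        return self.sequence[self.idblock_start - 1 : self.idblock_end]


@dataclass
class ReferenceDB:
    attbs: list[AttBRecord]
    gis: dict[str, GIRecord]
    integrases: dict[str, IntegraseRecord]  # pass-verdict only
    taxonomy: dict[str, tuple[str, str]]  # genome accession -> (species, genus)
    provenance: dict = field(default_factory=dict)

    def gi(self, gi_id: str) -> GIRecord:
        return self.gis[gi_id]


# ---------------------------------------------------------------------------
# integrity metric and family filters
# ---------------------------------------------------------------------------


def compute_ddha(hit: DomainHit, protein_length: int) -> int:
    """Truncation metric: HMM positions missing at the protein termini (dH)
    minus protein residues extending beyond the hit at the termini (dA).

    Large positive values mean the HMM is cut short without the protein
    offering residues to cover it, i.e. a truncated protein.
    """
    if hit.hmm_from > hit.hmm_to or hit.hmm_to > hit.hmm_length:
        raise ValueError(f"invalid HMM coordinates {hit.hmm_from}..{hit.hmm_to}/{hit.hmm_length}")
    if hit.ali_from > hit.ali_to:
        raise ValueError(f"invalid alignment coordinates {hit.ali_from}..{hit.ali_to}")
    if hit.ali_to > protein_length:
        raise ValueError(f"alignment end {hit.ali_to} beyond protein length {protein_length}")
    delta_h = (hit.hmm_from - 1) + (hit.hmm_length - hit.hmm_to)
    delta_a = (hit.ali_from - 1) + (protein_length - hit.ali_to)
    hit.delta_h = delta_h
    hit.delta_a = delta_a
    hit.ddha = delta_h - delta_a
    return hit.ddha


def _best(hits: Sequence[DomainHit]) -> DomainHit | None:
    return max(hits, key=lambda h: (h.score, h.hmm_name), default=None)


def filter_tyrosine(
    rec: IntegraseRecord,
    hits: Sequence[DomainHit],
    panel: frozenset[str] | set[str] = DEFAULT_TYROSINE_PANEL,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED,
    max_len: int = 800,
    ddha_cutoff: int = 100,
) -> IntegraseRecord:
    """Apply tyrosine-family integrity rules, setting verdict/reason in place."""
    if rec.family != TYROSINE:
        raise ValueError(f"{rec.protein_id}: not a tyrosine-family record")
    if not rec.sequence:
        raise ValueError(f"{rec.protein_id}: empty sequence")
    panel_hits = [h for h in hits if h.hmm_name in panel]
    best = _best(panel_hits)
    rec.best_hit = best
    if best is None:
        rec.verdict, rec.reject_reason = "reject", "no_hmm"
    elif best.hmm_name in excluded:
        rec.verdict, rec.reject_reason = "reject", "xer_or_integron"
    elif rec.length_aa > max_len:
        rec.verdict, rec.reject_reason = "reject", "too_long"
    elif compute_ddha(best, rec.length_aa) > ddha_cutoff:
        rec.verdict, rec.reject_reason = "reject", "truncated"
    else:
        rec.verdict, rec.reject_reason = "pass", "none"
    return rec


def filter_serine(
    rec: IntegraseRecord,
    hits: Sequence[DomainHit],
    max_len: int = 800,
    is607_max_len: int = 300,
    ddha_cutoff: int = 0,
) -> IntegraseRecord:
    """Apply serine-family integrity rules.

    A record passes either with the two-domain architecture (a Resolvase hit
    followed by a Recombinase hit, protein not over *max_len*, ddha not over
    *ddha_cutoff*) or as a pre-classified single-domain IS607-type enzyme
    (not over *is607_max_len*, same ddha rule).
    """
    if rec.family != SERINE:
        raise ValueError(f"{rec.protein_id}: not a serine-family record")
    if not rec.sequence:
        raise ValueError(f"{rec.protein_id}: empty sequence")
    best = _best(list(hits))
    rec.best_hit = best
    ddha = compute_ddha(best, rec.length_aa) if best is not None else None

    res = _best([h for h in hits if h.hmm_name == RESOLVASE])
    rcb = _best([h for h in hits if h.hmm_name == RECOMBINASE])
    has_architecture = res is not None and rcb is not None and res.ali_from < rcb.ali_from
    if has_architecture and rec.serine_class == "none":
        rec.serine_class = "resolvase_recombinase"

    if has_architecture and rec.length_aa <= max_len and ddha is not None and ddha <= ddha_cutoff:
        rec.verdict, rec.reject_reason = "pass", "none"
        return rec
    if (
        rec.serine_class == "s_core_is607"
        and rec.length_aa <= is607_max_len
        and ddha is not None
        and ddha <= ddha_cutoff
    ):
        rec.verdict, rec.reject_reason = "pass", "none"
        return rec

    # first failing reason of the branch the record was closest to
    rec.verdict = "reject"
    if rec.serine_class == "s_core_is607" and not has_architecture:
        if rec.length_aa > is607_max_len:
            rec.reject_reason = "too_long"
        elif ddha is not None and ddha > ddha_cutoff:
            rec.reject_reason = "truncated"
        else:
            rec.reject_reason = "no_hmm" if best is None else "bad_architecture"
    elif not has_architecture:
        rec.reject_reason = "no_hmm" if not hits else "bad_architecture"
    elif rec.length_aa > max_len:
        rec.reject_reason = "too_long"
    else:
        rec.reject_reason = "truncated"
    return rec


# ---------------------------------------------------------------------------
# attB dedup
# ---------------------------------------------------------------------------


def dedupe_attbs(gis: Iterable[GIRecord], min_len: int = 22) -> tuple[list[AttBRecord], int]:
    """Collapse GIs to one record per distinct uppercase attB sequence.

    Returns ``(records, n_dropped)`` where *n_dropped* counts distinct
    sequences below *min_len*.  When contributing GIs disagree on ID-block
    coordinates the highest-support GI wins (a warning is logged).
    """
    by_seq: dict[str, list[GIRecord]] = {}
    for gi in gis:
        by_seq.setdefault(gi.attb_seq.upper(), []).append(gi)

    records: list[AttBRecord] = []
    dropped = 0
    for i, (seq, group) in enumerate(by_seq.items()):
        if len(seq) < min_len:
            dropped += 1
            logger.warning("attB of length %d below floor %d dropped (GIs: %s)",
                           len(seq), min_len, ",".join(g.gi_id for g in group))
            continue
        champion = max(group, key=lambda g: (g.support_score, g.gi_id))
        coords = {(g.idblock_start, g.idblock_end) for g in group}
        if len(coords) > 1:
            logger.warning("attB %r: ID-block coordinate disagreement across %d GIs; "
                           "using highest-support GI %s", seq[:12] + "...", len(group), champion.gi_id)
        integrase_refs = sorted({pid for g in group for pid in g.integrase_ids})
        records.append(
            AttBRecord(
                attb_id=f"attb_{i + 1:06d}",
                sequence=seq,
                idblock_start=champion.idblock_start,
                idblock_end=champion.idblock_end,
                family="",  # assigned once cognate integrase families are known
                gi_refs=sorted(g.gi_id for g in group),
                integrase_refs=integrase_refs,
            )
        )
    return records, dropped


# ---------------------------------------------------------------------------
# input parsers
# ---------------------------------------------------------------------------

GI_TABLE_COLUMNS = [
    "gi_id",
    "contig_accession",
    "start",
    "end",
    "length",
    "support_score",
    "attb_seq",
    "idblock_start",
    "idblock_end",
    "target_class",
    "integrase_ids",
]


def parse_gi_table(path: str | Path) -> list[GIRecord]:
    records = []
    for row in iter_tsv(path):
        records.append(
            GIRecord(
                gi_id=row["gi_id"],
                contig_accession=row["contig_accession"],
                start=int(row["start"]),
                end=int(row["end"]),
                length=int(row["length"]),
                support_score=float(row["support_score"]),
                attb_seq=row["attb_seq"].upper(),
                idblock_start=int(row["idblock_start"]),
                idblock_end=int(row["idblock_end"]),
                target_class=row["target_class"],
                integrase_ids=[x for x in row["integrase_ids"].split(",") if x],
            )
        )
    return records


def write_gi_table(gis: Iterable[GIRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GI_TABLE_COLUMNS) + "\n")
        for g in gis:
            fh.write(
                "\t".join(
                    [
                        g.gi_id,
                        g.contig_accession,
                        str(g.start),
                        str(g.end),
                        str(g.length),
                        repr(g.support_score),
                        g.attb_seq,
                        str(g.idblock_start),
                        str(g.idblock_end),
                        g.target_class,
                        ",".join(g.integrase_ids),
                    ]
                )
                + "\n"
            )


def parse_domtblout(path: str | Path) -> dict[str, list[DomainHit]]:
    """Parse an hmmsearch-style per-domain table into protein -> hits.

    Orientation is hmmsearch (query = HMM, target = protein), so the HMM
    model length arrives in the query-length column.
    """
    hits: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        for qresult in SearchIO.parse(fh, "hmmsearch3-domtab"):
            for hit in qresult.hits:
                for hsp in hit.hsps:
                    hits.setdefault(hit.id, []).append(
                        DomainHit(
                            protein_id=hit.id,
                            hmm_name=qresult.id,
                            hmm_length=qresult.seq_len,
                            hmm_from=hsp.query_start + 1,  # SearchIO is 0-based half-open
                            hmm_to=hsp.query_end,
                            ali_from=hsp.hit_start + 1,
                            ali_to=hsp.hit_end,
                            score=float(hit.bitscore),
                        )
                    )
    return hits


def parse_taxonomy(path: str | Path) -> dict[str, tuple[str, str]]:
    return {
        row["genome_accession"]: (row["species"], row["genus"]) for row in iter_tsv(path)
    }


def parse_serine_classes(path: str | Path | None) -> dict[str, str]:
    """Optional TSV protein_id -> serine_class (external pre-classification)."""
    if path is None:
        return {}
    return {row["protein_id"]: row["serine_class"] for row in iter_tsv(path)}


# ---------------------------------------------------------------------------
# database build
# ---------------------------------------------------------------------------


def classify_family(hits: Sequence[DomainHit], serine_class: str) -> str:
    """Family call: serine when the record carries serine-domain evidence,
    tyrosine otherwise (the tyrosine filter then handles the no-hit case)."""
    if serine_class == "s_core_is607":
        return SERINE
    best_serine = _best([h for h in hits if h.hmm_name in SERINE_HMMS])
    best_other = _best([h for h in hits if h.hmm_name not in SERINE_HMMS])
    if best_serine is None:
        return TYROSINE
    if best_other is None:
        return SERINE
    return SERINE if best_serine.score >= best_other.score else TYROSINE


def build_reference_db(
    gi_table: str | Path,
    integrase_fasta: str | Path,
    domtblout: str | Path,
    taxonomy_table: str | Path,
    serine_class_table: str | Path | None = None,
    min_attb_len: int = 22,
    tyrosine_panel: frozenset[str] | set[str] = DEFAULT_TYROSINE_PANEL,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED,
) -> ReferenceDB:
    """Parse inputs, filter integrases, dedupe attBs and assemble the DB.

    Raises :class:`ReferenceError` if the GI table references a protein id
    absent from the FASTA.
    """
    gis = parse_gi_table(gi_table)
    proteins = read_fasta(integrase_fasta)
    domain_hits = parse_domtblout(domtblout)
    taxonomy = parse_taxonomy(taxonomy_table)
    serine_classes = parse_serine_classes(serine_class_table)

    if not gis:
        logger.warning("empty GI table: building an empty reference database")

    referenced = sorted({pid for g in gis for pid in g.integrase_ids})
    dangling = [pid for pid in referenced if pid not in proteins]
    if dangling:
        raise ReferenceError(
            "GI table references integrases missing from FASTA: " + ", ".join(dangling)
        )

    integrases: dict[str, IntegraseRecord] = {}
    reject_counts: dict[str, int] = {}
    for pid in referenced:
        seq = proteins[pid]
        hits = domain_hits.get(pid, [])
        sclass = serine_classes.get(pid, "none")
        family = classify_family(hits, sclass)
        rec = IntegraseRecord(
            protein_id=pid,
            sequence=seq,
            family=family,
            length_aa=len(seq),
            serine_class=sclass,
        )
        if family == TYROSINE:
            filter_tyrosine(rec, hits, panel=tyrosine_panel, excluded=excluded)
        else:
            filter_serine(rec, hits)
        integrases[pid] = rec
        if rec.verdict == "reject":
            reject_counts[rec.reject_reason] = reject_counts.get(rec.reject_reason, 0) + 1

    passing = {pid: r for pid, r in integrases.items() if r.verdict == "pass"}

    attbs, dropped = dedupe_attbs(gis, min_len=min_attb_len)
    queryable: list[AttBRecord] = []
    n_orphaned = 0
    for attb in attbs:
        cognates = [pid for pid in attb.integrase_refs if pid in passing]
        if not cognates:
            n_orphaned += 1
            continue
        families = [passing[pid].family for pid in cognates]
        # one family per attB drives flank-length choice; ties go to the
        # family of the first cognate in sorted id order
        attb.family = families[0]
        queryable.append(attb)

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "n_gis": len(gis),
        "n_integrases_in": len(referenced),
        "n_integrases_pass": len(passing),
        "reject_counts": reject_counts,
        "n_attbs": len(queryable),
        "n_attbs_dropped_short": dropped,
        "n_attbs_no_passing_integrase": n_orphaned,
        "min_attb_len": min_attb_len,
    }
    logger.info("reference DB: %d GIs in, %d/%d integrases pass, %d attBs queryable "
                "(%d short, %d without passing integrase)", len(gis), len(passing),
                len(referenced), len(queryable), dropped, n_orphaned)
    return ReferenceDB(
        attbs=queryable,
        gis={g.gi_id: g for g in gis},
        integrases=passing,
        taxonomy=taxonomy,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# serialization: JSON document + protein FASTA sidecar
# ---------------------------------------------------------------------------


def save_db(db: ReferenceDB, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "provenance": db.provenance,
        "attbs": [asdict(a) for a in db.attbs],
        "gis": [asdict(g) for g in db.gis.values()],
        "integrases": [
            {k: v for k, v in asdict(r).items() if k not in ("sequence", "best_hit")}
            | {"best_hit": asdict(r.best_hit) if r.best_hit else None}
            for r in db.integrases.values()
        ],
        "taxonomy": {k: list(v) for k, v in db.taxonomy.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    write_fasta({pid: r.sequence for pid, r in db.integrases.items()},
                path.with_suffix(".proteins.fasta"))


def load_db(path: str | Path) -> ReferenceDB:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ReferenceError(f"unsupported schema_version {doc.get('schema_version')!r}")
    proteins = read_fasta(path.with_suffix(".proteins.fasta"))
    integrases = {}
    for raw in doc["integrases"]:
        bh = raw.pop("best_hit", None)
        rec = IntegraseRecord(sequence=proteins[raw["protein_id"]],
                              best_hit=DomainHit(**bh) if bh else None, **raw)
        integrases[rec.protein_id] = rec
    return ReferenceDB(
        attbs=[AttBRecord(**a) for a in doc["attbs"]],
        gis={g["gi_id"]: GIRecord(**g) for g in doc["gis"]},
        integrases=integrases,
        taxonomy={k: (v[0], v[1]) for k, v in doc["taxonomy"].items()},
        provenance=doc["provenance"],
    )
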