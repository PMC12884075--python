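"""Synthetic genomes, reference databases and planted-truth fixtures.

Everything the pipeline consumes can be generated here deterministically
from a seed: random genomes, reference GI tables with fabricated domain-hit
tables (the integrity filters read coordinates and scores, not residues),
taxonomy tables, reference-genome FASTAs, and target genomes with planted
attB candidates, occupied sites and decoys whose expected classification is
recorded in a truth table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from iod._util import revcomp, write_fasta
from iod.registry import (
    AttBRecord,
    GIRecord,
    ReferenceDB,
    SERINE,
    TYROSINE,
    build_reference_db,
    save_db,
    write_gi_table,
)
from iod.sketch import save_sketches, sketch_genome

BASES = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureTruth:
    seed: int
    planted_candidates: list[dict] = field(default_factory=list)
    planted_occupied: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)

    def all_loci(self) -> list[tuple[str, int, int]]:
        out = []
        for rec in self.planted_candidates + self.planted_occupied + self.decoys:
            out.append((rec["contig"], rec["start"], rec["end"]))
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "FixtureTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# random sequence primitives
# ---------------------------------------------------------------------------


def random_genome(length: int, gc: float = 0.5, seed: int = 0, contig: str = "contig_1") -> dict[str, str]:
    """A single-contig i.i.d. random genome at the given GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])
    return {contig: seq}


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, len(AA), size=length)])


def _clean_filler(rng: np.random.Generator, length: int, avoid: list[str], gc: float = 0.5) -> str:
    """Random DNA rejection-sampled to contain no sequence in *avoid* (either strand)."""
    for _ in range(50):
        s = random_dna(rng, length, gc)
        if not any(a in s or revcomp(a) in s for a in avoid if a):
            return s
    raise RuntimeError("could not sample filler avoiding the given motifs")


def _with_edits(seq: str, n_mismatch: int, n_gap: int, rng: np.random.Generator) -> str:
    """Apply exactly the stated substitution and deletion counts."""
    s = list(seq)
    if n_gap:
        for pos in sorted(rng.choice(np.arange(1, len(s) - 1), size=n_gap, replace=False), reverse=True):
            del s[pos]
    if n_mismatch:
        for pos in rng.choice(len(s), size=n_mismatch, replace=False):
            s[pos] = rng.choice([b for b in BASES if b != s[pos]])
    return "".join(s)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


class PlantError(ValueError):
    pass


def _check_free(truth: FixtureTruth, contig: str, start: int, end: int) -> None:
    for c, s, e in truth.all_loci():
        if c == contig and start <= e and s <= end:
            raise PlantError(f"locus {contig}:{start}-{end} overlaps prior plant {c}:{s}-{e}")


def _splice(genome: dict[str, str], contig: str, pos: int, insert: str) -> dict[str, str]:
    g = dict(genome)
    seq = g[contig]
    if pos + len(insert) > len(seq):
        raise PlantError(f"plant of {len(insert)} nt at {contig}:{pos + 1} does not fit")
    g[contig] = seq[:pos] + insert + seq[pos + len(insert):]
    return g


def plant_attb(
    genome: dict[str, str],
    attb: AttBRecord,
    contig: str,
    pos: int,
    edits: tuple[int, int] = (0, 0),
    seed: int = 0,
    truth: FixtureTruth | None = None,
    kind: str = "candidate",
) -> dict[str, str]:
    """Write (optionally mutated) *attb* into the genome at 0-based *pos*.

    ``edits = (n_mismatch, n_gap)``; gaps are single-base deletions so the
    planted region sits at exactly that banded edit distance from the attB.
    """
    rng = np.random.default_rng(seed)
    planted = _with_edits(attb.sequence, *edits, rng=rng)
    start, end = pos + 1, pos + len(planted)
    if truth is not None:
        _check_free(truth, contig, start, end)
    genome = _splice(genome, contig, pos, planted)
    if truth is not None:
        rec = {"attb_id": attb.attb_id, "contig": contig, "start": start, "end": end,
               "kind": kind, "edits": list(edits)}
        if kind == "candidate":
            truth.planted_candidates.append(rec)
        else:
            truth.decoys.append(rec)
    return genome


def half_sites(attb: AttBRecord, sl: int = 16, yl: int = 10) -> tuple[str, str]:
    """Left/right half-site sequences exactly as the query builder makes them."""
    fl = sl if attb.family == SERINE else yl
    seq = attb.sequence
    left = seq[max(0, attb.idblock_start - 1 - fl): attb.idblock_end]
    right = seq[attb.idblock_start - 1: attb.idblock_end + fl]
    return left, right


def plant_occupied(
    genome: dict[str, str],
    attb: AttBRecord,
    gi_length: int,
    contig: str,
    pos: int,
    filler_seed: int = 0,
    truth: FixtureTruth | None = None,
    sl: int = 16,
    yl: int = 10,
    avoid: list[str] | None = None,
    kind: str = "occupied",
) -> dict[str, str]:
    """Plant ``attB_left-half .. filler .. attB_right-half`` spanning *gi_length* nt."""
    rng = np.random.default_rng(filler_seed)
    left, right = half_sites(attb, sl, yl)
    filler_len = gi_length - len(left) - len(right)
    if filler_len < 0:
        raise PlantError(f"gi_length {gi_length} shorter than the two half sites")
    filler = _clean_filler(rng, filler_len, (avoid or []) + [attb.idblock_seq])
    block = left + filler + right
    start, end = pos + 1, pos + gi_length
    if truth is not None:
        _check_free(truth, contig, start, end)
    genome = _splice(genome, contig, pos, block)
    if truth is not None:
        rec = {"attb_id": attb.attb_id, "contig": contig, "start": start, "end": end,
               "kind": kind, "gi_length": gi_length}
        if kind == "occupied":
            truth.planted_occupied.append(rec)
        else:
            truth.decoys.append(rec)
    return genome


def plant_occupied_split(
    genome: dict[str, str],
    attb: AttBRecord,
    gi_length: int,
    left_contig: str,
    right_contig: str,
    filler_seed: int = 0,
    truth: FixtureTruth | None = None,
    sl: int = 16,
    yl: int = 10,
    avoid: list[str] | None = None,
) -> dict[str, str]:
    """Split an occupied site across two contig termini.

    The left half site goes near the end of *left_contig* (island running
    through its right terminus) and the right half near the start of
    *right_contig*, sized so the two terminal distances sum to *gi_length*.
    """
    rng = np.random.default_rng(filler_seed)
    left, right = half_sites(attb, sl, yl)
    avoid_all = (avoid or []) + [attb.idblock_seq]
    dist_l = gi_length // 2
    dist_r = gi_length - dist_l
    fill_l = dist_l - len(left)
    fill_r = dist_r - len(right)
    if fill_l < 0 or fill_r < 0:
        raise PlantError("gi_length too short for a split plant")
    g = dict(genome)
    la = len(g[left_contig])
    block_l = left + _clean_filler(rng, fill_l, avoid_all)
    g = _splice(g, left_contig, la - dist_l, block_l)
    block_r = _clean_filler(rng, fill_r, avoid_all) + right
    g = _splice(g, right_contig, 0, block_r)
    if truth is not None:
        truth.planted_occupied.append(
            {"attb_id": attb.attb_id, "contig": left_contig, "start": la - dist_l + 1,
             "end": la, "kind": "occupied_split", "gi_length": gi_length,
             "right_contig": right_contig}
        )
    return g


# ---------------------------------------------------------------------------
# synthetic reference database
# ---------------------------------------------------------------------------

_DOMTBL_HEADER = (
    "#                                                               --- full sequence --- "
    "-------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   E-value  "
    "score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    "
    "to  acc description of target\n"
)


def write_domtblout(rows: list[dict], path: str | Path) -> None:
    """Write fabricated hmmsearch per-domain rows (query = HMM, target = protein)."""
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for r in rows:
            fh.write(
                f"{r['protein_id']} - {r['protein_len']} {r['hmm_name']} - {r['hmm_length']} "
                f"1e-50 {r['score']:.1f} 0.1 1 1 1e-50 1e-50 {r['score']:.1f} 0.1 "
                f"{r['hmm_from']} {r['hmm_to']} {r['ali_from']} {r['ali_to']} "
                f"{r['ali_from']} {r['ali_to']} 0.98 -\n"
            )


@dataclass
class SynthDB:
    outdir: Path
    paths: dict[str, Path]
    db: ReferenceDB
    ref_genomes: dict[str, dict[str, str]]  # accession -> contig -> seq
    base_genomes: dict[str, dict[str, str]]  # accession -> genome before attB plants
    db_path: Path


def _make_attb(rng: np.random.Generator, family: str, idblock: str | None = None) -> tuple[str, int, int]:
    """Random attB sequence; returns (seq, idblock_start, idblock_end)."""
    ib = idblock if idblock is not None else random_dna(rng, int(rng.integers(16, 21)))
    lf = random_dna(rng, int(rng.integers(12, 21)))
    rf = random_dna(rng, int(rng.integers(12, 21)))
    seq = lf + ib + rf
    return seq, len(lf) + 1, len(lf) + len(ib)


def synth_reference_db(
    outdir: str | Path,
    n_species: int = 3,
    attbs_per_species: int = 16,
    seed: int = 0,
    ref_genome_len: int = 30_000,
    serine_fraction: float = 0.25,
    special_attbs: list[str] | None = None,
    special_integrases: list[str] | None = None,
) -> SynthDB:
    """Generate all reference inputs, build the DB, and serialize it.

    ``special_attbs`` kinds: ``homopolymer_idblock`` (12xA identity block),
    ``short`` (sub-floor attB, dropped at dedup).  ``special_integrases``
    kinds exercise filter branches: ``tyr_ddha_120``, ``tyr_ddha_5``,
    ``tyr_too_long``, ``no_hmm``, ``xer``, ``serine_swapped``, ``is607_ok``.
    Each special adds one extra GI/attB/integrase triple to the last species.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gis: list[GIRecord] = []
    proteins: dict[str, str] = {}
    dom_rows: list[dict] = []
    serine_classes: list[tuple[str, str]] = []
    taxonomy_rows: list[tuple[str, str, str]] = []
    ref_genomes: dict[str, dict[str, str]] = {}
    base_genomes: dict[str, dict[str, str]] = {}

    def add_entry(acc: str, contig: str, idx: int, family: str, attb_seq: str,
                  ib_start: int, ib_end: int, pos: int, kind: str = "normal") -> None:
        gi_id = f"{acc}|gene{idx:04d}"
        pid = f"{acc}_p{idx:04d}"
        gi_len = int(rng.integers(5_000, 50_001))
        support = round(float(rng.uniform(1.0, 10.0)), 2)
        gis.append(
            GIRecord(
                gi_id=gi_id,
                contig_accession=contig,
                start=pos + 1,
                end=pos + gi_len,
                length=gi_len,
                support_score=support,
                attb_seq=attb_seq,
                idblock_start=ib_start,
                idblock_end=ib_end,
                target_class=str(rng.choice(["tRNA", "tmRNA", "intergenic", "protein_coding"])),
                integrase_ids=[pid],
            )
        )
        _add_integrase(pid, family, kind)

    def _add_integrase(pid: str, family: str, kind: str) -> None:
        if kind == "tyr_ddha_120":
            plen = 180
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Y-Int",
                                 hmm_length=300, hmm_from=121, hmm_to=300,
                                 ali_from=1, ali_to=plen, score=80.0))
        elif kind == "tyr_ddha_5":
            plen = 295
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Y-Int",
                                 hmm_length=300, hmm_from=6, hmm_to=300,
                                 ali_from=1, ali_to=plen, score=150.0))
        elif kind == "tyr_too_long":
            plen = 850
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Y-Int",
                                 hmm_length=300, hmm_from=1, hmm_to=300,
                                 ali_from=200, ali_to=499, score=200.0))
        elif kind == "no_hmm":
            proteins[pid] = random_protein(rng, 400)
        elif kind == "xer":
            plen = 300
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Xer",
                                 hmm_length=298, hmm_from=1, hmm_to=298,
                                 ali_from=1, ali_to=298, score=250.0))
        elif kind == "serine_swapped":
            plen = 500
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Recombinase",
                                 hmm_length=250, hmm_from=1, hmm_to=250,
                                 ali_from=10, ali_to=259, score=220.0))
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Resolvase",
                                 hmm_length=120, hmm_from=1, hmm_to=120,
                                 ali_from=300, ali_to=419, score=120.0))
        elif kind == "is607_ok":
            plen = 250
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="S-Core_IS607",
                                 hmm_length=250, hmm_from=1, hmm_to=250,
                                 ali_from=1, ali_to=plen, score=180.0))
            serine_classes.append((pid, "s_core_is607"))
        elif family == SERINE:
            plen = int(rng.integers(450, 551))
            proteins[pid] = random_protein(rng, plen)
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Resolvase",
                                 hmm_length=120, hmm_from=1, hmm_to=120,
                                 ali_from=5, ali_to=124, score=float(rng.uniform(80, 150))))
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Recombinase",
                                 hmm_length=250, hmm_from=1, hmm_to=250,
                                 ali_from=150, ali_to=399, score=float(rng.uniform(150, 280))))
        else:
            plen = int(rng.integers(350, 451))
            proteins[pid] = random_protein(rng, plen)
            start = int(rng.integers(1, plen - 300 + 2))
            dom_rows.append(dict(protein_id=pid, protein_len=plen, hmm_name="Y-Int",
                                 hmm_length=300, hmm_from=1, hmm_to=300,
                                 ali_from=start, ali_to=start + 299,
                                 score=float(rng.uniform(100, 300))))

    idx = 0
    for sp in range(n_species):
        acc = f"GCA_{900000 + sp:06d}.1"
        contig = f"{acc}_c1"
        species = f"Species_{sp:02d}"
        genus = f"Genus_{sp // 2:02d}"
        taxonomy_rows.append((acc, species, genus))
        base = random_genome(ref_genome_len, gc=0.5, seed=seed * 1000 + sp, contig=contig)
        base_genomes[acc] = dict(base)
        genome = dict(base)
        spacing = ref_genome_len // (attbs_per_species + 1)
        for j in range(attbs_per_species):
            family = SERINE if rng.random() < serine_fraction else TYROSINE
            attb_seq, ib_s, ib_e = _make_attb(rng, family)
            pos = spacing * (j + 1)
            genome = _splice(genome, contig, pos, attb_seq)
            add_entry(acc, contig, idx, family, attb_seq, ib_s, ib_e, pos)
            idx += 1
        ref_genomes[acc] = genome

    # specials land on the last species
    acc = f"GCA_{900000 + n_species - 1:06d}.1"
    contig = f"{acc}_c1"
    for kind in special_attbs or []:
        if kind == "homopolymer_idblock":
            attb_seq, ib_s, ib_e = _make_attb(rng, TYROSINE, idblock="A" * 12)
        elif kind == "short":
            attb_seq, ib_s, ib_e = random_dna(rng, 20), 3, 14
        else:
            raise ValueError(f"unknown special attB kind {kind!r}")
        add_entry(acc, contig, idx, TYROSINE, attb_seq, ib_s, ib_e, pos=25, kind=kind)
        idx += 1
    for kind in special_integrases or []:
        family = SERINE if kind in ("serine_swapped", "is607_ok") else TYROSINE
        attb_seq, ib_s, ib_e = _make_attb(rng, family)
        add_entry(acc, contig, idx, family, attb_seq, ib_s, ib_e, pos=60, kind=kind)
        idx += 1

    paths = {
        "gi_table": outdir / "gi_table.tsv",
        "integrases": outdir / "integrases.fasta",
        "domtblout": outdir / "domains.domtblout",
        "taxonomy": outdir / "taxonomy.tsv",
        "serine_classes": outdir / "serine_classes.tsv",
        "manifest": outdir / "ref_manifest.tsv",
    }
    write_gi_table(gis, paths["gi_table"])
    write_fasta(proteins, paths["integrases"])
    write_domtblout(dom_rows, paths["domtblout"])
    with open(paths["taxonomy"], "w") as fh:
        fh.write("genome_accession\tspecies\tgenus\n")
        for acc_, sp_, ge_ in taxonomy_rows:
            fh.write(f"{acc_}\t{sp_}\t{ge_}\n")
    with open(paths["serine_classes"], "w") as fh:
        fh.write("protein_id\tserine_class\n")
        for pid, cls in serine_classes:
            fh.write(f"{pid}\t{cls}\n")

    genome_dir = outdir / "ref_genomes"
    genome_dir.mkdir(exist_ok=True)
    with open(paths["manifest"], "w") as fh:
        fh.write("genome_accession\tpath\n")
        for acc_, genome in ref_genomes.items():
            p = genome_dir / f"{acc_}.fasta"
            write_fasta(genome, p)
            fh.write(f"{acc_}\t{p}\n")

    db = build_reference_db(
        paths["gi_table"], paths["integrases"], paths["domtblout"], paths["taxonomy"],
        serine_class_table=paths["serine_classes"],
    )
    db_path = outdir / "reference_db.json"
    save_db(db, db_path)
    paths["db"] = db_path
    return SynthDB(outdir=outdir, paths=paths, db=db, ref_genomes=ref_genomes,
                   base_genomes=base_genomes, db_path=db_path)


# ---------------------------------------------------------------------------
# planted-truth fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    dir: Path
    synth: SynthDB
    genome: dict[str, str]
    genome_path: Path
    sketches_path: Path
    truth: FixtureTruth
    truth_path: Path


def _attbs_sorted(db: ReferenceDB) -> list[AttBRecord]:
    return sorted(db.attbs, key=lambda a: a.attb_id)


def build_fixture(
    outdir: str | Path,
    seed: int = 1,
    n_species: int = 3,
    attbs_per_species: int = 16,
    target_len: int = 120_000,
    n_candidates: int = 5,
    occupied_gi_lengths: tuple[int, ...] = (9_000, 13_000),
    with_decoys: bool = True,
) -> Fixture:
    """A target genome with planted candidates, occupied sites and decoys.

    The target shares its backbone with the first reference species (so
    taxonomic ranking puts that species first) but carries none of that
    species' attBs except the planted ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = synth_reference_db(
        outdir / "refdb",
        n_species=n_species,
        attbs_per_species=attbs_per_species,
        seed=seed,
        special_attbs=["homopolymer_idblock"] if with_decoys else None,
    )
    db = synth.db
    rng = np.random.default_rng(seed + 10_000)
    truth = FixtureTruth(seed=seed)

    first_acc = sorted(synth.base_genomes)[0]
    base_contig = next(iter(synth.base_genomes[first_acc]))
    base_seq = synth.base_genomes[first_acc][base_contig]
    contig = "target_contig_1"
    reps = target_len // len(base_seq) + 1
    pad = random_dna(rng, max(0, target_len - len(base_seq)))
    genome = {contig: (base_seq + pad)[:target_len]}

    attbs = _attbs_sorted(db)
    homopoly = [a for a in attbs if set(a.idblock_seq) == {"A"}]
    normal = [a for a in attbs if a not in homopoly]
    avoid = [a.idblock_seq for a in attbs]

    picks = list(rng.choice(len(normal), size=n_candidates + len(occupied_gi_lengths) + 3, replace=False))
    cursor = 2_000

    def take_pos(size: int) -> int:
        nonlocal cursor
        pos = cursor + int(rng.integers(500, 2_000))
        cursor = pos + size
        if cursor >= target_len:
            raise PlantError("target genome too small for requested plants")
        return pos

    # planted clean candidates
    for i in range(n_candidates):
        attb = normal[picks[i]]
        pos = take_pos(len(attb.sequence))
        genome = plant_attb(genome, attb, contig, pos, edits=(0, 0),
                            seed=seed + i, truth=truth, kind="candidate")

    # planted occupied sites, sized exactly to their best reference GI
    occ_attbs = []
    for i, gi_len in enumerate(occupied_gi_lengths):
        attb = normal[picks[n_candidates + i]]
        ref_gi = max((db.gis[g] for g in attb.gi_refs), key=lambda g: g.support_score)
        ref_gi.length = gi_len  # align the reference length to the planted span
        ref_gi.end = ref_gi.start + gi_len - 1
        pos = take_pos(gi_len)
        genome = plant_occupied(genome, attb, gi_len, contig, pos,
                                filler_seed=seed + 100 + i, truth=truth, avoid=avoid)
        occ_attbs.append(attb)

    if with_decoys:
        k = n_candidates + len(occupied_gi_lengths)
        # near-length island: span 0.0526 off every reference GI length
        decoy = normal[picks[k]]
        ref_gi = max((db.gis[g] for g in decoy.gi_refs), key=lambda g: g.support_score)
        expected = 10_000
        for g in decoy.gi_refs:
            db.gis[g].length = expected
            db.gis[g].end = db.gis[g].start + expected - 1
        actual = 9_000  # nd = 1000/19000 = 0.0526 > 0.05
        pos = take_pos(actual)
        genome = plant_occupied(genome, decoy, actual, contig, pos,
                                filler_seed=seed + 200, truth=truth, avoid=avoid,
                                kind="near_length_gi")

        # multi-copy ID block: a clean attB plus a stray copy of its ID block
        decoy2 = normal[picks[k + 1]]
        pos = take_pos(len(decoy2.sequence))
        genome = plant_attb(genome, decoy2, contig, pos, seed=seed + 300,
                            truth=truth, kind="multi_idblock")
        pos = take_pos(len(decoy2.idblock_seq))
        genome = _splice(genome, contig, pos, decoy2.idblock_seq)
        truth.decoys.append({"attb_id": decoy2.attb_id, "contig": contig,
                             "start": pos + 1, "end": pos + len(decoy2.idblock_seq),
                             "kind": "idblock_copy"})

        # mutated beyond the mismatch bound: invisible to the matcher
        decoy3 = normal[picks[k + 2]]
        pos = take_pos(len(decoy3.sequence))
        genome = plant_attb(genome, decoy3, contig, pos, edits=(3, 0),
                            seed=seed + 400, truth=truth, kind="mutated_3mm")

        # homopolymer ID block attB planted cleanly
        if homopoly:
            pos = take_pos(len(homopoly[0].sequence))
            genome = plant_attb(genome, homopoly[0], contig, pos, seed=seed + 500,
                                truth=truth, kind="homopolymer")

    # regenerated DB copy with adjusted GI lengths
    save_db(db, synth.db_path)

    genome_path = outdir / "target_genome.fasta"
    write_fasta(genome, genome_path)
    sketches = [
        sketch_genome(list(g.values()), genome_id=acc)
        for acc, g in sorted(synth.ref_genomes.items())
    ]
    sketches_path = outdir / "ref_sketches.jsonl"
    save_sketches(sketches, sketches_path)
    truth_path = outdir / "truth.json"
    truth.save(truth_path)
    return Fixture(dir=outdir, synth=synth, genome=genome, genome_path=genome_path,
                   sketches_path=sketches_path, truth=truth, truth_path=truth_path)


def standard_fixture(outdir: str | Path, seed: int = 1) -> Fixture:
    """The canonical test fixture: 3 species, ~50 attBs, 5 planted candidates,
    2 planted occupied sites, and the full decoy set."""
    return build_fixture(outdir, seed=seed)


def random_fixture(outdir: str | Path, seed: int) -> Fixture:
    """A smaller randomized fixture for conservation audits."""
    return build_fixture(
        outdir,
        seed=seed,
        n_species=2,
        attbs_per_species=8,
        target_len=40_000,
        n_candidates=2,
        occupied_gi_lengths=(6_000,),
        with_decoys=False,
    )
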