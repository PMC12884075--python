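"""MinHash genome sketching and taxonomic neighbor selection.

A genome is reduced to the bottom-s set of 64-bit hashes over its canonical
k-mers; the sketch Jaccard estimate between two genomes converts to a
distance d = -ln(2j/(1+j))/k.  Reference genomes are ranked by distance to
the target and attB records are collected species-by-species from the
nearest relatives until a minimum query-set size is reached.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from iod.registry import AttBRecord, ReferenceDB

DEFAULT_K = 21
DEFAULT_S = 1000
DEFAULT_SEED = 42

_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
    _BASE_LUT[ord(chr(_b).lower())] = _i

_CHUNK = 1 << 18


@dataclass
class Sketch:
    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted ascending uint64, |hashes| <= s
    genome_length: int

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)


@dataclass
class NeighborRank:
    genome_id: str
    jaccard_estimate: float
    distance: float
    species: str = ""
    genus: str = ""


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (wrapping uint64 arithmetic)."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of canonical k-mers (lexicographic min of k-mer and its
    reverse complement); windows containing non-ACGT are skipped."""
    arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    pow4 = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    out = []
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        win = np.lib.stride_tricks.sliding_window_view(arr[lo : hi + k - 1], k)
        ok = (win != 255).all(axis=1)
        w = win[ok].astype(np.uint64)
        if w.size == 0:
            continue
        fwd = (w * pow4).sum(axis=1, dtype=np.uint64)
        rev = ((np.uint64(3) - w[:, ::-1]) * pow4).sum(axis=1, dtype=np.uint64)
        out.append(np.minimum(fwd, rev))
    if not out:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(out)


def sketch_genome(
    seqs: Iterable[str],
    genome_id: str = "",
    k: int = DEFAULT_K,
    s: int = DEFAULT_S,
    seed: int = DEFAULT_SEED,
) -> Sketch:
    """Bottom-s MinHash sketch over the canonical k-mers of a sequence set."""
    seqs = list(seqs)
    total = sum(len(x) for x in seqs)
    codes = [ _canonical_kmer_codes(x, k) for x in seqs if len(x) >= k ]
    codes = [c for c in codes if c.size]
    if not codes:
        raise ValueError(f"genome {genome_id!r}: no valid k-mer of length {k} "
                         f"(total sequence {total} nt)")
    salt = np.uint64((seed * 0x2545F4914F6CDD1D) % (1 << 64))
    hashes = _splitmix64(np.concatenate(codes) ^ salt)
    hashes = np.unique(hashes)[:s]
    return Sketch(genome_id=genome_id, k=k, s=s, hashes=hashes, genome_length=total)


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Distance from the Jaccard estimate of the merged bottom-s sketch.

    j = 0 is capped at distance 1.0 (the log form is undefined there).
    """
    if a.k != b.k or a.s != b.s:
        raise ValueError(f"incompatible sketches: k={a.k}/{b.k}, s={a.s}/{b.s}")
    merged = np.union1d(a.hashes, b.hashes)
    s_prime = min(a.s, merged.size)
    bottom = merged[:s_prime]
    shared = int(np.isin(bottom, a.hashes).sum() + np.isin(bottom, b.hashes).sum() - s_prime)
    j = shared / s_prime if s_prime else 0.0
    if j <= 0.0:
        return 1.0
    d = -math.log(2.0 * j / (1.0 + j)) / a.k
    return min(max(d, 0.0), 1.0)


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    merged = np.union1d(a.hashes, b.hashes)
    s_prime = min(a.s, merged.size)
    if s_prime == 0:
        return 0.0
    bottom = merged[:s_prime]
    shared = int(np.isin(bottom, a.hashes).sum() + np.isin(bottom, b.hashes).sum() - s_prime)
    return shared / s_prime


def rank_neighbors(
    target: Sketch,
    refs: Sequence[Sketch],
    taxonomy: dict[str, tuple[str, str]] | None = None,
) -> list[NeighborRank]:
    """Rank reference sketches by ascending distance to *target*; ties break
    lexicographically on genome_id so the ranking is deterministic."""
    if not refs:
        raise ValueError("no reference sketches supplied")
    ranks = []
    for ref in refs:
        j = jaccard_estimate(target, ref)
        d = mash_distance(target, ref)
        species, genus = ("", "")
        if taxonomy and ref.genome_id in taxonomy:
            species, genus = taxonomy[ref.genome_id]
        ranks.append(NeighborRank(ref.genome_id, j, d, species, genus))
    ranks.sort(key=lambda r: (r.distance, r.genome_id))
    return ranks


def collect_attbs(
    ranked: Sequence[NeighborRank],
    db: ReferenceDB,
    n_min: int = 500,
) -> list[AttBRecord]:
    """Assemble the taxonomic-mode query set.

    Whole-species attB blocks are added atomically: first the species of the
    best-ranked genome, then remaining species of that genus in rank order,
    then further genera by rank, stopping at the first block that brings the
    running count to at least *n_min* (or when sources are exhausted).
    Species contributing no attBs do not count as blocks.
    """
    if not db.attbs:
        import logging

        logging.getLogger(__name__).warning("collect_attbs: empty reference DB")
        return []

    species_rank: dict[str, int] = {}
    genus_rank: dict[str, int] = {}
    species_genus: dict[str, str] = {}
    for i, nb in enumerate(ranked):
        species, genus = nb.species, nb.genus
        if not species and nb.genome_id in db.taxonomy:
            species, genus = db.taxonomy[nb.genome_id]
        if not species:
            continue
        species_rank.setdefault(species, i)
        genus_rank.setdefault(genus, i)
        species_genus.setdefault(species, genus)

    attbs_by_species: dict[str, list[AttBRecord]] = {}
    for attb in db.attbs:
        seen: set[str] = set()
        for gi_ref in attb.gi_refs:
            gi = db.gis.get(gi_ref)
            if gi is None:
                continue
            tax = db.taxonomy.get(gi.genome_accession)
            if tax and tax[0] not in seen:
                seen.add(tax[0])
                attbs_by_species.setdefault(tax[0], []).append(attb)

    order = sorted(
        species_rank,
        key=lambda sp: (genus_rank[species_genus[sp]], species_rank[sp], sp),
    )
    collected: list[AttBRecord] = []
    seen_ids: set[str] = set()
    for sp in order:
        block = [a for a in attbs_by_species.get(sp, []) if a.attb_id not in seen_ids]
        if not block:
            continue
        for a in block:
            seen_ids.add(a.attb_id)
            collected.append(a)
        if len(collected) >= n_min:
            break
    return collected


# ---------------------------------------------------------------------------
# sketch cache (JSON lines, one sketch per line)
# ---------------------------------------------------------------------------


def save_sketches(sketches: Iterable[Sketch], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(
                json.dumps(
                    {
                        "genome_id": sk.genome_id,
                        "k": sk.k,
                        "s": sk.s,
                        "genome_length": sk.genome_length,
                        "hashes": [int(h) for h in sk.hashes],
                    }
                )
                + "\n"
            )


def load_sketches(path: str | Path) -> list[Sketch]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            out.append(
                Sketch(
                    genome_id=doc["genome_id"],
                    k=doc["k"],
                    s=doc["s"],
                    hashes=np.array(doc["hashes"], dtype=np.uint64),
                    genome_length=doc["genome_length"],
                )
            )
    return out
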