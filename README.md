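# iod

Find native landing pads for site-specific integration in prokaryotic
genomes. Given a target genome and a reference collection of genomic-island
derived attB/integrase pairs, `iod` identifies unoccupied, high-quality attB
sites (and their cognate integrases) by:

1. **registry** — building a searchable reference database: parsing a GI
   table, integrase FASTA and HMMER domtblout; applying family-specific
   integrity filters (tyrosine: HMM panel membership, Xer/Integron
   exclusion, 800-aa cap, the ΔΔHA > 100 truncation cutoff; serine:
   Resolvase-then-Recombinase architecture or IS607-type single-domain
   class, ΔΔHA ≤ 0); and deduplicating attB sequences (22-nt floor).
2. **sketch** — ranking reference genomes by MinHash distance
   (k=21, s=1000, d = −ln(2j/(1+j))/k) and collecting attBs
   species-by-species from the nearest relatives until the query set reaches
   a minimum size (default n = 500).
3. **match** — locating each attB and its two half sites (left flank +
   ID block, ID block + right flank; flank 16 nt for serine, 10 nt for
   tyrosine) on both strands with at most 2 mismatches and 1 gap column
   over the full query. The seed-and-extend matcher is exact under those
   bounds (verified against a brute-force per-offset oracle).
4. **classify** — rejecting hits below 95% identity / over the edit caps;
   routing attBs with multiple loci to occupancy inference, where observed
   half-site separations are tested against reference GI lengths with the
   normalized difference (expected − actual)/(expected + actual) at a 0.05
   threshold (cross-contig half-site pairs use hit orientation to pick
   contig termini); demoting candidates inside occupied sites, with
   multi-copy ID blocks, or with ≥10-nt homopolymer ID blocks; and binning
   overlapping candidates, ranking winners by reference-GI support.
5. **reports** — writing `final_candidates.tsv`, `attb_dupes.tsv`,
   `occupied.tsv` and `isles.json`.

A sixth module, **simdata**, generates fully synthetic inputs — genomes,
reference databases, fabricated domain-hit tables and planted-truth
fixtures — so everything is testable offline.

## CLI

```sh
# generate a synthetic fixture (genome + reference DB + sketches + truth)
iod simulate --preset standard --seed 1 --out fixture/

# build a reference DB from raw inputs
iod build-db --gi-table gi.tsv --integrases ints.fa --domtblout hits.tbl \
             --taxonomy tax.tsv --out db.json

# sketch reference genomes listed in a manifest TSV (genome_accession, path)
iod sketch --manifest refs.tsv --out sketches.jsonl

# taxonomic mode: query attBs from the target's nearest relatives
iod taxonomic --genome target.fa --db db.json --sketches sketches.jsonl \
              --n 500 --sl 16 --yl 10 --threads 1 --out run/

# search mode: query a chosen attB id list (or the whole DB)
iod search --genome target.fa --db db.json --attb-list ids.txt --out run/
```

All run options can also be supplied via `--config config.yaml`
(explicit flags win). Outputs are deterministic for a fixed config and
seed, independent of thread count.

### Input formats

- **GI table**: TSV with columns `gi_id, contig_accession, start, end,
  length, support_score, attb_seq, idblock_start, idblock_end,
  target_class, integrase_ids` (1-based inclusive coordinates; `gi_id` is
  `<genome accession>|<gene id>`; `integrase_ids` comma-joined).
- **Integrase proteins**: FASTA keyed by protein id.
- **Domain hits**: HMMER3 domtblout, hmmsearch orientation (query = HMM).
- **Taxonomy**: TSV `genome_accession, species, genus`.
- **Reference DB**: JSON document plus a `.proteins.fasta` sidecar.

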