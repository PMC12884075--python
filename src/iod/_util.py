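"""Small shared helpers: sequence utilities and FASTA I/O."""

from __future__ import annotations

import decimal
import gzip
from pathlib import Path
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passed through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> sequence map.

    Only the first whitespace-delimited token of each header is kept as the id.
    Sequences are uppercased.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_tsv(path: str | Path) -> Iterator[dict[str, str]]:
    """Iterate rows of a header-ed TSV file as dicts."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            yield dict(zip(header, line.split("\t")))


def homopolymer_run(seq: str) -> int:
    """Length of the longest single-nucleotide run in *seq*."""
    best = 0
    run = 0
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run > best:
            best = run
    return best


def sig3(x: float) -> float:
    """Round to three significant figures with decimal half-up rounding.

    The value is first rendered at 12 significant digits to drop binary
    float noise (1.835e-4 stored as 1.8349999...e-4 must round like the
    decimal 1.835e-4), then rounded half-up as printed arithmetic would be.
    """
    if x == 0:
        return 0.0
    d = decimal.Decimal(f"{x:.12g}")
    shift = d.adjusted()
    q = d.scaleb(-shift).quantize(decimal.Decimal("1.00"), rounding=decimal.ROUND_HALF_UP)
    return float(q.scaleb(shift))
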