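"""Shared I/O and seed plumbing.

FASTQ records are streamed lazily as :class:`FastqRead`; tables are plain
TSV (tab-separated, header row, ``NA`` for missing) handled through pandas.
All stage-level randomness derives from one named seed via
:func:`stage_rng`, so any pipeline stage can be rerun in isolation and
still reproduce its output byte for byte.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Malformed FASTQ input; message carries the 1-based line number."""


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    seq: str
    qual: str  # Phred+33 ASCII, same length as seq

    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an integer array."""
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Lazily yield reads from a (optionally gzipped) Phred+33 FASTQ file.

    Raises :class:`FastqParseError` with the offending line number on a
    truncated record, a bad header/separator, or a seq/qual length mismatch.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"{path}: line {lineno}: expected '@' record header")
            lines = [fh.readline() for _ in range(3)]
            if any(l == "" for l in lines):
                raise FastqParseError(f"{path}: line {lineno}: truncated record")
            seq, plus, qual = (l.rstrip("\n") for l in lines)
            if not plus.startswith("+"):
                raise FastqParseError(f"{path}: line {lineno + 2}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno + 3}: sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)})"
                )
            lineno += 3
            yield FastqRead(header[1:].split()[0], seq, qual)


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV table ('.' decimal, 'NA' missing), validating required columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed (< 2^31) from a global seed and stage name."""
    digest = hashlib.sha256(f"{stage}:{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A Generator whose stream is keyed by (global seed, stage name)."""
    return np.random.default_rng(stage_seed(seed, stage))


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
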