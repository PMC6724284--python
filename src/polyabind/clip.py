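"""CLIP-seq processing and PAB-binding-efficiency computation.

The preprocessing order is fixed (and tested): PCR-duplicate collapse on
full read sequences (barcode included) -> 5' barcode removal -> 3' A-tract
trimming -> >=18-nt length filter -> unique assignment to a transcript
3' region.  Binding efficiency (BE) of a gene is its CLIP reads per
million assigned reads divided by its mRNA FPKM; genes below an expression
floor are omitted rather than producing unstable or infinite ratios.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FastqRead


def deduplicate_reads(reads: Iterable[FastqRead]) -> list[FastqRead]:
    """Collapse byte-identical sequences to one read, keeping first occurrence.

    Duplicates are judged on the full sequence including the 4-nt random
    barcode, so reads differing only in barcode are distinct molecules.
    """
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def strip_barcode(read: FastqRead, n: int = 4) -> FastqRead:
    """Remove the n-nt random 5' barcode (after deduplication)."""
    if len(read.seq) <= n:
        raise ValueError(f"read {read.read_id} shorter than barcode length {n}")
    return FastqRead(read.read_id, read.seq[n:], read.qual[n:])


def trim_3prime_a_tract(seq: str) -> str:
    """Remove the maximal 3'-terminal run of A; an empty result is allowed."""
    return seq.rstrip("A")


class ThreePrimeIndex:
    """Unique substring lookup over transcript 3' regions.

    A trimmed CLIP read is assigned to the unique gene whose 3'-terminal
    ``region`` nt contain the read as an exact substring.
    """

    def __init__(self, transcripts: Mapping[str, str], region: int = 200, k: int = 18):
        self.k = k
        self.regions: dict[str, str] = {}
        self.offsets: dict[str, int] = {}
        self.lengths: dict[str, int] = {}
        self._by_kmer: dict[str, set[str]] = defaultdict(set)
        for gene, seq in transcripts.items():
            reg = seq[-region:]
            self.regions[gene] = reg
            self.offsets[gene] = len(seq) - len(reg)
            self.lengths[gene] = len(seq)
            for i in range(len(reg) - k + 1):
                self._by_kmer[reg[i : i + k]].add(gene)

    def locate(self, read: str, min_len: int = 18):
        """(gene_id, absolute start, scaled position) of a unique match, else None."""
        if len(read) < max(min_len, self.k):
            return None
        hits = []
        for gene in self._by_kmer.get(read[: self.k], ()):
            pos = self.regions[gene].find(read)
            if pos >= 0:
                hits.append((gene, self.offsets[gene] + pos))
        if len(hits) != 1:
            return None
        gene, start = hits[0]
        return gene, start, start / self.lengths[gene]


def filter_and_assign(
    trimmed: Iterable[str],
    index: ThreePrimeIndex,
    min_len: int = 18,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Length-filter trimmed reads and assign them to genes.

    Returns (per-gene count table, scaled positions of assigned reads).
    Reads shorter than ``min_len`` or without a unique match are discarded.
    """
    counts: dict[str, int] = defaultdict(int)
    positions = []
    for seq in trimmed:
        if len(seq) < min_len:
            continue
        hit = index.locate(seq, min_len=min_len)
        if hit is None:
            continue
        gene, _, frac = hit
        counts[gene] += 1
        positions.append(frac)
    table = pd.DataFrame(
        sorted(counts.items()), columns=["gene_id", "clip_reads"]
    )
    return table, np.asarray(positions)


def _max_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def classify_oligoA(seqs: Iterable[str], k: int = 12) -> dict[str, float]:
    """Fraction of reads containing >= k consecutive copies of each base.

    A-rich reads dominating this summary is the signature of PAB-bound
    poly(A) capture (a 12-nt run being one PAB footprint).
    """
    seqs = list(seqs)
    if not seqs:
        return {b: 0.0 for b in "ACGT"}
    return {
        b: float(np.mean([_max_run(s, b) >= k for s in seqs])) for b in "ACGT"
    }


def compute_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million assigned reads; Sum(RPM) = 1e6 by construction."""
    total = counts["clip_reads"].sum()
    if total <= 0:
        raise ValueError("no assigned reads")
    out = counts.copy()
    out["clip_rpm"] = counts["clip_reads"] * 1e6 / total
    return out


def binding_efficiency(
    rpm: pd.DataFrame, fpkm: pd.DataFrame, min_fpkm: float = 1.0
) -> pd.DataFrame:
    """Per-gene binding efficiency BE = CLIP RPM / mRNA FPKM.

    Genes absent from either table or at/below the expression floor are
    omitted with a reason column rather than reported with unstable ratios.
    """
    merged = rpm.merge(fpkm[["gene_id", "fpkm"]], on="gene_id", how="left")
    merged = merged.rename(columns={"fpkm": "mrna_fpkm"})
    reason = np.where(
        merged["mrna_fpkm"].isna(), "missing_fpkm",
        np.where(merged["mrna_fpkm"] <= min_fpkm, "below_fpkm_floor", ""),
    )
    merged["omit_reason"] = reason
    ok = merged["omit_reason"] == ""
    merged["binding_efficiency"] = np.where(
        ok, merged["clip_rpm"] / merged["mrna_fpkm"], np.nan
    )
    return merged


def metagene_profile(positions: Sequence[float], bins: int = 100) -> np.ndarray:
    """Density of scaled read positions over [0, 1), normalized to sum 1."""
    pos = np.clip(np.asarray(positions, float), 0.0, np.nextafter(1.0, 0.0))
    hist, _ = np.histogram(pos, bins=bins, range=(0.0, 1.0))
    total = hist.sum()
    if total == 0:
        raise ValueError("no positions to profile")
    return hist / total


def cross_sample_binding_correlation(
    be_tables: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Pairwise Pearson r of log10 binding efficiency over shared genes."""
    names = list(be_tables)
    series = {
        name: tbl.dropna(subset=["binding_efficiency"])
        .set_index("gene_id")["binding_efficiency"]
        for name, tbl in be_tables.items()
    }
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = series[a].index.intersection(series[b].index)
            if len(shared) < 3:
                r = np.nan
            else:
                r, _ = stats.pearsonr(
                    np.log10(series[a].loc[shared]), np.log10(series[b].loc[shared])
                )
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def run_clip_pipeline(
    reads: Iterable[FastqRead],
    transcripts: Mapping[str, str],
    fpkm: pd.DataFrame,
    barcode_n: int = 4,
    min_len: int = 18,
    min_fpkm: float = 1.0,
    region: int = 200,
):
    """dedup -> barcode strip -> A-trim -> length filter -> assign -> BE.

    Returns (BE table, scaled positions, oligo-A classification of the
    deduplicated reads).
    """
    unique = deduplicate_reads(reads)
    oligo = classify_oligoA(r.seq for r in unique)
    stripped = [strip_barcode(r, barcode_n) for r in unique]
    trimmed = [trim_3prime_a_tract(r.seq) for r in stripped]
    index = ThreePrimeIndex(transcripts, region=region, k=min_len)
    counts, positions = filter_and_assign(trimmed, index, min_len=min_len)
    be = binding_efficiency(compute_rpm(counts), fpkm, min_fpkm=min_fpkm)
    return be, positions, oligo
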