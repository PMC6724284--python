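"""Poly(A)-tail calling from 3'-adaptor-ligated sequencing reads.

A tail-sequencing read has the layout::

    5'  [3-nt random prefix][3'-UTR insert][poly(A) tail][3' adaptor...]  3'

The tail is recovered as the longest suffix of the adaptor-proximal insert
consisting of A plus a small allowed set of non-A bases (G by default, at
most ``max_non_a`` of them), and is accepted only when its first
``min_lead_a`` bases are all A.  Guanosines interrupt the tail into maximal
A-tracts; a poly(A)-binding protein footprint needs 12 consecutive A, so a
tail's PAB capacity is the number of non-overlapping footprints its tracts
can hold.  Per-gene aggregates (G%, median tail length, exclusive-A
fraction, mean capacity) feed the downstream binding/translation analyses.

Coordinates are 0-based half-open; tail positions count from the tail's
5' end.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FastqRead, PHRED_OFFSET

DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"

#: rejection reason codes used by the read-level pipeline
REASONS = (
    "short_read",      # read too short to strip the random prefix
    "no_adaptor",      # no recognizable 3' adaptor
    "empty_insert",    # adaptor starts at position 0, nothing upstream
    "no_tail",         # no qualifying A/G suffix on the insert
    "short_lead_a",    # tail's first min_lead_a bases are not all A
    "low_g_quality",   # some G in the tail has Phred below threshold
    "short_insert",    # trimmed insert shorter than min_insert
    "unassigned",      # no unique exact transcript 3'-suffix match
)


class TailRejection(Exception):
    """A read failed tail calling; ``reason`` is one of :data:`REASONS`."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class TailCall:
    """One called poly(A) tail."""

    tail_seq: str
    read_id: str | None = None
    gene_id: str | None = None
    adaptor_found: bool = True
    passes_quality: bool | None = None
    g_min_quality: int | None = None

    def __post_init__(self):
        self.tail_length: int = len(self.tail_seq)
        self.g_positions: tuple[int, ...] = tuple(
            i for i, c in enumerate(self.tail_seq) if c == "G"
        )
        self.g_count: int = len(self.g_positions)
        self.a_tracts: tuple[int, ...] = a_tract_decomposition(self.tail_seq)
        self.non_a_count: int = self.tail_length - self.tail_seq.count("A")

    @property
    def capacity(self) -> int:
        return pab_capacity(self.a_tracts)

    @property
    def g_percent(self) -> float:
        return read_g_percent(self)


def strip_random_prefix(seq: str, qual: str | None = None, n: int = 3):
    """Remove the n-nt random 5' prefix (and its qualities, in lockstep)."""
    if len(seq) <= n:
        raise TailRejection("short_read")
    if qual is None:
        return seq[n:]
    return seq[n:], qual[n:]


def _mismatches_within(fragment: str, seq: str, offset: int, limit: int) -> bool:
    mm = 0
    for j in range(len(fragment)):
        if seq[offset + j] != fragment[j]:
            mm += 1
            if mm > limit:
                return False
    return True


def find_adaptor(
    seq: str,
    adaptor: str = DEFAULT_ADAPTOR,
    min_prefix: int = 10,
    max_mismatch: int = 1,
) -> int | None:
    """Locate the 3' adaptor: leftmost suffix-anchored occurrence.

    A match is either the full adaptor internal to the read, or an adaptor
    prefix of >= ``min_prefix`` nt ending exactly at the read's 3' terminus,
    in both cases with at most ``max_mismatch`` substitutions.  Returns the
    0-based start position, or None.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    n, m = len(seq), len(adaptor)
    # fast path: an exact full occurrence bounds the leftmost match
    exact = seq.find(adaptor)
    limit = exact if exact >= 0 else n
    for i in range(min(limit, n)):
        if i + m <= n:
            if _mismatches_within(adaptor, seq, i, max_mismatch):
                return i
        else:
            k = n - i
            if k < min_prefix:
                break
            if _mismatches_within(adaptor[:k], seq, i, max_mismatch):
                return i
    return exact if exact >= 0 else None


def call_tail(
    insert: str,
    max_non_a: int = 5,
    min_lead_a: int = 5,
    allowed_non_a: frozenset[str] = frozenset("G"),
) -> TailCall:
    """Call the poly(A) tail as the longest qualifying suffix of the insert.

    The tail is the longest suffix over ``{A} | allowed_non_a`` containing
    at most ``max_non_a`` non-A bases; it is accepted iff its first
    ``min_lead_a`` bases are all A.  Raises :class:`TailRejection`
    otherwise.
    """
    if not insert:
        raise ValueError("insert must be non-empty")
    allowed = frozenset("A") | allowed_non_a
    non_a = 0
    start = len(insert)
    for i in range(len(insert) - 1, -1, -1):
        c = insert[i]
        if c not in allowed:
            break
        if c != "A":
            if non_a + 1 > max_non_a:
                break
            non_a += 1
        start = i
    tail = insert[start:]
    if not tail:
        raise TailRejection("no_tail")
    if len(tail) < min_lead_a or tail[:min_lead_a] != "A" * min_lead_a:
        raise TailRejection("short_lead_a")
    return TailCall(tail_seq=tail)


def quality_filter_tail(
    call: TailCall, tail_quals: Sequence[int] | np.ndarray, min_g_quality: int = 20
) -> bool:
    """True iff every G in the tail has Phred >= min_g_quality.

    All-A tails always pass.  ``tail_quals`` are integer Phred scores
    aligned to ``call.tail_seq``.
    """
    quals = np.asarray(tail_quals)
    if len(quals) != call.tail_length:
        raise ValueError(
            f"quality vector length {len(quals)} != tail length {call.tail_length}"
        )
    if not call.g_positions:
        call.passes_quality = True
        call.g_min_quality = None
        return True
    gq = quals[list(call.g_positions)]
    call.g_min_quality = int(gq.min())
    call.passes_quality = bool(call.g_min_quality >= min_g_quality)
    return call.passes_quality


class TranscriptIndex:
    """Exact 3'-terminal suffix lookup over a transcript set.

    An insert is assigned to the unique gene whose transcript sequence ends
    with the insert; ambiguous or unmatched inserts return None.
    """

    def __init__(self, transcripts: Mapping[str, str], key_len: int = 18):
        self.transcripts = dict(transcripts)
        self.key_len = key_len
        self._by_suffix: dict[str, list[str]] = defaultdict(list)
        for gene, seq in self.transcripts.items():
            self._by_suffix[seq[-key_len:]].append(gene)

    def assign(self, insert: str, min_len: int = 18) -> str | None:
        if len(insert) < min_len:
            return None
        if len(insert) >= self.key_len:
            candidates = self._by_suffix.get(insert[-self.key_len :], ())
        else:  # pragma: no cover - only reachable with min_len < key_len
            candidates = list(self.transcripts)
        hits = [g for g in candidates if self.transcripts[g].endswith(insert)]
        return hits[0] if len(hits) == 1 else None


def assign_to_gene(insert: str, index: TranscriptIndex, min_len: int = 18) -> str | None:
    """Assign a tail-trimmed insert to a gene by unique exact 3'-suffix match."""
    return index.assign(insert, min_len=min_len)


def read_g_percent(call: TailCall) -> float:
    """G content of one tail, in percent of tail length."""
    return 100.0 * call.g_count / call.tail_length


_A_RUN = re.compile(r"A+")


def a_tract_decomposition(tail_seq: str) -> tuple[int, ...]:
    """Lengths of the maximal A-runs of a tail, 5' to 3'."""
    return tuple(len(m.group()) for m in _A_RUN.finditer(tail_seq))


def pab_capacity(a_tracts: Iterable[int], footprint: int = 12) -> int:
    """Number of PAB footprints the tail's A-tracts can hold.

    Each maximal A-tract of length L holds floor(L / footprint)
    non-overlapping footprints; tracts shorter than the footprint hold none.
    """
    return int(sum(t // footprint for t in a_tracts))


def process_polya_reads(
    reads: Iterable[FastqRead],
    index: TranscriptIndex,
    adaptor: str = DEFAULT_ADAPTOR,
    prefix_n: int = 3,
    min_prefix: int = 10,
    max_mismatch: int = 1,
    max_non_a: int = 5,
    min_lead_a: int = 5,
    min_g_quality: int = 20,
    min_insert: int = 18,
    allowed_non_a: frozenset[str] = frozenset("G"),
) -> pd.DataFrame:
    """Run the full per-read tail-calling pipeline.

    Returns one row per input read; accepted reads have ``reject_reason``
    NA and carry the called tail, its gene and capacity.  The pipeline
    order is: strip random prefix -> locate adaptor -> call tail ->
    G-quality filter -> trim tail -> length filter -> gene assignment.
    """
    rows = []

    def reject(read_id: str, reason: str):
        rows.append(
            dict(
                read_id=read_id, gene_id=None, tail_seq=None, tail_length=None,
                g_count=None, g_positions=None, capacity=None, reject_reason=reason,
            )
        )

    for read in reads:
        try:
            seq, qual = strip_random_prefix(read.seq, read.qual, prefix_n)
        except TailRejection as e:
            reject(read.read_id, e.reason)
            continue
        pos = find_adaptor(seq, adaptor, min_prefix=min_prefix, max_mismatch=max_mismatch)
        if pos is None:
            reject(read.read_id, "no_adaptor")
            continue
        if pos == 0:
            reject(read.read_id, "empty_insert")
            continue
        insert = seq[:pos]
        try:
            call = call_tail(insert, max_non_a, min_lead_a, allowed_non_a)
        except TailRejection as e:
            reject(read.read_id, e.reason)
            continue
        phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET
        tail_quals = phred[len(insert) - call.tail_length : len(insert)]
        if not quality_filter_tail(call, tail_quals, min_g_quality):
            reject(read.read_id, "low_g_quality")
            continue
        trimmed = insert[: len(insert) - call.tail_length]
        if len(trimmed) < min_insert:
            reject(read.read_id, "short_insert")
            continue
        gene = index.assign(trimmed, min_len=min_insert)
        if gene is None:
            reject(read.read_id, "unassigned")
            continue
        call.read_id = read.read_id
        call.gene_id = gene
        rows.append(
            dict(
                read_id=read.read_id, gene_id=gene, tail_seq=call.tail_seq,
                tail_length=call.tail_length, g_count=call.g_count,
                g_positions=";".join(map(str, call.g_positions)),
                capacity=call.capacity, reject_reason=None,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "tail_seq", "tail_length", "g_count",
                 "g_positions", "capacity", "reject_reason"],
    )


def accepted_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Subset of the per-read table that passed every filter."""
    return calls[calls["reject_reason"].isna()].copy()


def aggregate_gene_profiles(calls: pd.DataFrame, footprint: int = 12) -> pd.DataFrame:
    """Per-gene tail statistics over accepted, assigned calls.

    G% of a gene is total G over total tail length (x100), which equals the
    tail-length-weighted mean of per-read G%.  Median tail length, the
    fraction of tails containing any G, the exclusive-A fraction, the
    fraction of tails with at least one bindable (>= footprint) A-tract,
    and the mean PAB capacity are reported alongside.
    """
    acc = accepted_calls(calls)
    if acc.empty:
        return pd.DataFrame(
            columns=["gene_id", "n_tails", "g_percent", "median_tail_length",
                     "frac_tails_with_g", "frac_exclusive_a",
                     "has_bindable_fraction", "mean_capacity"]
        )
    acc = acc.assign(
        non_a=acc["tail_seq"].map(lambda s: len(s) - s.count("A")),
        bindable=acc["tail_seq"].map(
            lambda s: int(any(t >= footprint for t in a_tract_decomposition(s)))
        ),
    )
    grp = acc.groupby("gene_id", sort=True)
    out = pd.DataFrame(
        {
            "n_tails": grp.size(),
            "g_percent": 100.0 * grp["g_count"].sum() / grp["tail_length"].sum(),
            "median_tail_length": grp["tail_length"].median(),
            "frac_tails_with_g": grp["g_count"].apply(lambda g: float((g > 0).mean())),
            "frac_exclusive_a": grp["non_a"].apply(lambda v: float((v == 0).mean())),
            "has_bindable_fraction": grp["bindable"].mean(),
            "mean_capacity": grp["capacity"].mean(),
        }
    ).reset_index()
    return out


def tail_composition_stats(calls: pd.DataFrame) -> dict:
    """Library-wide composition summary over accepted calls.

    Returns the fraction of tails with any non-A base, with any G, the
    fraction of genes whose tails ever contain a G, and the per-gene G%
    range among G-containing genes.
    """
    acc = accepted_calls(calls)
    if acc.empty:
        return dict(frac_tails_non_a=0.0, frac_tails_with_g=0.0,
                    frac_genes_with_g=0.0, g_percent_min=np.nan, g_percent_max=np.nan)
    non_a = acc["tail_seq"].map(lambda s: len(s) - s.count("A"))
    profiles = aggregate_gene_profiles(calls)
    with_g = profiles[profiles["g_percent"] > 0]
    return dict(
        frac_tails_non_a=float((non_a > 0).mean()),
        frac_tails_with_g=float((acc["g_count"] > 0).mean()),
        frac_genes_with_g=float((profiles["g_percent"] > 0).mean()),
        g_percent_min=float(with_g["g_percent"].min()) if len(with_g) else np.nan,
        g_percent_max=float(with_g["g_percent"].max()) if len(with_g) else np.nan,
    )
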