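"""Seeded generator for every pipeline input, with recorded ground truth.

The generator emulates the statistical structure the downstream analyses
assume: per-gene poly(A) tails whose lengths are discretized truncated
normal and whose bases carry i.i.d. guanosine insertions at a gene-specific
rate (a configurable fraction of genes never inserts G); CLIP libraries
whose per-gene read counts scale with mRNA level times a binding affinity
that increases with the tail's expected PAB capacity; ribosome footprints
with 3-nt periodicity whose abundance scales with mRNA level times
translational efficiency (itself coupled to binding affinity); exponential
mRNA decay with lognormal noise, decay rates drawn independently of
binding; paralog pairs differing in G-insertion rate; and a proteome in
which protein = mRNA x TE x noise.

All randomness flows from ``SimConfig.seed`` through stage-keyed
substreams, so each simulated artifact is byte-identical across runs and
independent of the other stages.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FastqRead, stage_rng
from .tails import DEFAULT_ADAPTOR

BASES = "ACGT"


class SimulationError(RuntimeError):
    """The generator could not satisfy a structural guarantee."""


@dataclass
class SimConfig:
    """Knobs of the generative model.

    Defaults are the study conditions the analyses are exercised under:
    median tail ~50 nt, two thirds of genes never insert G, G-insertion
    rates spanning 0.8%-28% per base among G-genes, 150-nt reads carrying
    the TGGAATTCTCGGGTGCCAAGG 3' adaptor, decay sampled at
    t = 0, 0.5, 1, 2, 4, 8 h in 3 replicates.
    """

    n_genes: int = 2000
    seed: int = 42
    # tails
    tail_length_median: float = 50.0
    tail_length_sd: float = 15.0
    tail_median_spread: float = 10.0  # gene-to-gene spread of the median
    zero_g_gene_fraction: float = 0.66
    g_rate_range: tuple[float, float] = (0.008, 0.28)
    # poly(A)-seq reads
    seq_error_rate: float = 0.001
    reads_per_gene_mean: float = 20.0
    read_length: int = 150
    adaptor: str = DEFAULT_ADAPTOR
    prefix_n: int = 3
    insert_length_range: tuple[int, int] = (20, 60)
    # transcriptome
    transcript_length_range: tuple[int, int] = (300, 600)
    utr5_length_range: tuple[int, int] = (10, 40)
    utr3_min: int = 60
    # CLIP
    binding_affinity_slope: float = 1.0
    clip_reads_per_gene_mean: float = 200.0
    clip_barcode_n: int = 4
    clip_body_length_range: tuple[int, int] = (20, 40)
    clip_atract_length_range: tuple[int, int] = (12, 30)
    clip_duplicate_rate: float = 0.15
    # expression / dynamics
    mrna_level_median: float = 10.0
    mrna_level_sigma: float = 1.0
    noise_sd: float = 0.1  # lognormal sigma on counts/FPKM-scale tables
    decay_rate_range: tuple[float, float] = (0.05, 1.5)
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_replicates: int = 3
    # translation
    te_coupling: float = 1.0
    te_noise_sd: float = 0.4
    mutant_te_knockdown: float = 0.5
    ribo_reads_per_gene_mean: float = 300.0
    frame0_fraction: float = 0.9
    # paralogs
    paralog_min_g_offset: float = 0.01

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("zero_g_gene_fraction", "seq_error_rate", "frame0_fraction",
                     "clip_duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("g_rate_range", "decay_rate_range", "insert_length_range",
                     "transcript_length_range", "clip_body_length_range",
                     "clip_atract_length_range", "utr5_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        if not 0.0 <= self.g_rate_range[0] <= 1.0 or not 0.0 <= self.g_rate_range[1] <= 1.0:
            raise ValueError("g_rate_range entries must be probabilities")
        min_structure = self.prefix_n + self.insert_length_range[0] + 1 + 10
        if self.read_length < min_structure:
            raise ValueError(
                f"read_length {self.read_length} cannot hold prefix + minimum "
                f"insert + tail + recognizable adaptor (needs >= {min_structure})"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth of one simulated study: per-gene parameters + transcripts."""

    config: SimConfig
    genes: pd.DataFrame  # one row per gene, indexed 0..n-1, column gene_id
    transcripts: dict[str, str]

    def transcript_lengths(self) -> pd.Series:
        return pd.Series({g: len(s) for g, s in self.transcripts.items()}, name="length")

    def cds_lengths(self) -> pd.Series:
        g = self.genes.set_index("gene_id")
        return (g["cds_end"] - g["cds_start"]).rename("cds_length")


def _tail_length_grid(median: float, sd: float, n: int = 199) -> np.ndarray:
    """Deterministic quantile grid of the discretized truncated-normal tail length."""
    probs = (np.arange(n) + 0.5) / n
    lengths = np.rint(stats.norm.ppf(probs, loc=median, scale=sd))
    return np.maximum(lengths, 1.0)


def expected_capacity(g_rate: float, tail_median: float, tail_sd: float,
                      footprint: int = 12) -> float:
    """Expected PAB capacity of a gene's tails under the i.i.d.-G model.

    For a tail of length L with per-base G probability p, the expected
    number of maximal A-runs of length >= j is (1-p)^j (1 + (L-j) p), and
    capacity = sum over tracts of floor(len/footprint) =
    sum_{m>=1} #runs >= m*footprint.  The tail-length distribution is
    integrated over a deterministic quantile grid.
    """
    lengths = _tail_length_grid(tail_median, tail_sd)
    if g_rate <= 0:
        return float(np.mean(np.floor(lengths / footprint)))
    out = np.zeros_like(lengths)
    max_m = int(lengths.max() // footprint)
    for m in range(1, max_m + 1):
        j = m * footprint
        mask = lengths >= j
        out[mask] += (1 - g_rate) ** j * (1 + (lengths[mask] - j) * g_rate)
    return float(np.mean(out))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def generate_truth(config: SimConfig) -> SimTruth:
    """Draw the per-gene ground truth and the synthetic transcriptome.

    Transcripts are random sequences whose 3'-terminal base is C or T (so
    the tail/insert boundary is identifiable) and whose 3'-terminal 30-mers
    are pairwise distinct (so exact suffix assignment is unambiguous); CDS
    length is a multiple of 3 and leaves a 3' UTR of at least
    ``config.utr3_min`` nt.
    """
    rng = stage_rng(config.seed, "truth")
    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]

    transcripts: dict[str, str] = {}
    seen_30mers: set[str] = set()
    cds_start = np.zeros(n, dtype=int)
    cds_end = np.zeros(n, dtype=int)
    budget = 100 + 10 * n
    for i, gid in enumerate(gene_ids):
        for _ in range(budget):
            L = int(rng.integers(*config.transcript_length_range, endpoint=True))
            seq = _random_seq(rng, L - 1) + ("C" if rng.random() < 0.5 else "T")
            if seq[-30:] not in seen_30mers:
                break
        else:
            raise SimulationError("could not generate distinct 3'-terminal 30-mers")
        seen_30mers.add(seq[-30:])
        transcripts[gid] = seq
        utr5 = int(rng.integers(*config.utr5_length_range, endpoint=True))
        coding_room = (L - utr5 - config.utr3_min) // 3
        if coding_room < 1:
            raise SimulationError(f"transcript {gid} too short for a CDS")
        n_codons = int(rng.integers(1, coding_room, endpoint=True))
        cds_start[i] = utr5
        cds_end[i] = utr5 + 3 * n_codons

    zero_g = rng.random(n) < config.zero_g_gene_fraction
    lo, hi = config.g_rate_range
    if lo <= 0:
        raise ValueError("g_rate_range low bound must be > 0 for log-uniform draws")
    g_rate = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    g_rate[zero_g] = 0.0

    tail_median = np.clip(
        rng.normal(config.tail_length_median, config.tail_median_spread, size=n), 20.0, None
    )
    tail_sd = np.full(n, config.tail_length_sd)

    ecap = np.array([
        expected_capacity(g_rate[i], tail_median[i], tail_sd[i]) for i in range(n)
    ])
    affinity = 1.0 + config.binding_affinity_slope * ecap

    mrna_level = rng.lognormal(np.log(config.mrna_level_median),
                               config.mrna_level_sigma, size=n)
    decay_rate = rng.uniform(*config.decay_rate_range, size=n)

    rel_aff = affinity / affinity.mean()
    true_te = rel_aff ** config.te_coupling * rng.lognormal(0.0, config.te_noise_sd, size=n)
    true_te_mut = true_te * np.exp(-config.mutant_te_knockdown * rel_aff)

    genes = pd.DataFrame(
        dict(
            gene_id=gene_ids, cds_start=cds_start, cds_end=cds_end,
            g_insertion_rate=g_rate, tail_length_median=tail_median,
            tail_length_sd=tail_sd, expected_capacity=ecap,
            binding_affinity=affinity, mrna_level=mrna_level,
            true_decay_rate=decay_rate, true_te=true_te, true_te_mut=true_te_mut,
            paralog_partner=[None] * n,
        )
    )
    return SimTruth(config=config, genes=genes, transcripts=transcripts)


def generate_transcriptome(config: SimConfig):
    """Annotation table (gene_id, cds_start, cds_end; 0-based half-open) + FASTA dict."""
    truth = generate_truth(config)
    annotation = truth.genes[["gene_id", "cds_start", "cds_end"]].copy()
    return annotation, truth.transcripts


def simulate_tail(g_rate: float, tail_median: float, tail_sd: float,
                  rng: np.random.Generator) -> str:
    """One tail: discretized truncated-normal length, i.i.d. G at g_rate."""
    length = max(1, int(round(rng.normal(tail_median, tail_sd))))
    if g_rate <= 0:
        return "A" * length
    mask = rng.random(length) < g_rate
    return "".join("G" if m else "A" for m in mask)


def _phred_string(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


_OTHER = {b: BASES.replace(b, "") for b in BASES}


def simulate_polya_seq(truth: SimTruth, config: SimConfig | None = None,
                       seq_error_rate: float | None = None):
    """Poly(A)-seq FASTQ reads plus a per-read truth table.

    Each read is: 3-nt random prefix + 3'-UTR suffix + tail + adaptor,
    truncated to ``read_length``; substitution errors at ``seq_error_rate``
    (erroneous bases get lower Phred scores, mimicking miscall/quality
    correlation).  The truth table records the gene, the true tail, and how
    many adaptor bases survived truncation.
    """
    config = config or truth.config
    rate = config.seq_error_rate if seq_error_rate is None else seq_error_rate
    rng = stage_rng(config.seed, "polya_seq")
    reads: list[FastqRead] = []
    truth_rows = []
    counter = itertools.count(1)
    for row in truth.genes.itertuples(index=False):
        tx = truth.transcripts[row.gene_id]
        n_reads = rng.poisson(config.reads_per_gene_mean)
        for _ in range(n_reads):
            prefix = _random_seq(rng, config.prefix_n)
            ins_len = int(rng.integers(*config.insert_length_range, endpoint=True))
            ins_len = min(ins_len, len(tx))
            insert = tx[-ins_len:]
            tail = simulate_tail(row.g_insertion_rate, row.tail_length_median,
                                 row.tail_length_sd, rng)
            full = prefix + insert + tail + config.adaptor
            seq = full[: config.read_length]
            adaptor_bases = max(0, len(seq) - (config.prefix_n + ins_len + len(tail)))
            quals = np.clip(np.rint(rng.normal(38, 2, size=len(seq))), 2, 40).astype(int)
            if rate > 0:
                err = rng.random(len(seq)) < rate
                if err.any():
                    chars = list(seq)
                    for i in np.flatnonzero(err):
                        chars[i] = _OTHER[chars[i]][rng.integers(0, 3)]
                        quals[i] = int(np.clip(round(rng.normal(20, 5)), 2, 40))
                    seq = "".join(chars)
            rid = f"pa{next(counter):07d}"
            reads.append(FastqRead(rid, seq, _phred_string(quals)))
            truth_rows.append(dict(read_id=rid, gene_id=row.gene_id, true_tail=tail,
                                   insert_length=ins_len, adaptor_bases=adaptor_bases))
    return reads, pd.DataFrame(truth_rows)


def simulate_clip_library(truth: SimTruth, config: SimConfig | None = None,
                          emit_reads: bool = True):
    """CLIP-seq reads and per-gene expected/emitted molecule counts.

    Per-gene unique molecule counts are Poisson with mean proportional to
    mRNA level x binding affinity.  Each molecule is a 4-nt random barcode,
    a 3'-UTR-derived body, and a 3'-terminal A-tract; PCR re-emits each
    molecule Geometric(1 - duplicate_rate) times, so the expected fraction
    of duplicate reads equals ``clip_duplicate_rate``.
    """
    config = config or truth.config
    rng = stage_rng(config.seed, "clip_seq")
    weight = truth.genes["mrna_level"] * truth.genes["binding_affinity"]
    lam = config.clip_reads_per_gene_mean * weight / weight.mean()
    molecules = rng.poisson(lam.to_numpy())
    counts = pd.DataFrame(dict(
        gene_id=truth.genes["gene_id"], expected_count=lam.to_numpy(),
        unique_molecules=molecules,
    ))
    if not emit_reads:
        return None, counts
    reads: list[FastqRead] = []
    counter = itertools.count(1)
    for gid, n_mol in zip(truth.genes["gene_id"], molecules):
        tx = truth.transcripts[gid]
        for _ in range(n_mol):
            barcode = _random_seq(rng, config.clip_barcode_n)
            body_len = int(rng.integers(*config.clip_body_length_range, endpoint=True))
            body = tx[-min(body_len, len(tx)):]
            a_len = int(rng.integers(*config.clip_atract_length_range, endpoint=True))
            seq = barcode + body + "A" * a_len
            copies = (rng.geometric(1.0 - config.clip_duplicate_rate)
                      if config.clip_duplicate_rate > 0 else 1)
            qual = _phred_string(np.full(len(seq), 38))
            for _ in range(copies):
                reads.append(FastqRead(f"cl{next(counter):07d}", seq, qual))
    return reads, counts


def simulate_expression_table(truth: SimTruth, config: SimConfig | None = None,
                              label: str = "mrna") -> pd.DataFrame:
    """An mRNA-seq-style FPKM table: true level x lognormal noise."""
    config = config or truth.config
    rng = stage_rng(config.seed, f"expr_{label}")
    noise = rng.lognormal(0.0, config.noise_sd, size=len(truth.genes))
    return pd.DataFrame(dict(gene_id=truth.genes["gene_id"],
                             fpkm=truth.genes["mrna_level"].to_numpy() * noise))


def simulate_decay_course(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Tidy FPKM table over the shutoff time course x replicates.

    FPKM(t) = mRNA(0) * exp(-k t) * lognormal(0, noise_sd), independently
    per time point and replicate.
    """
    config = config or truth.config
    rng = stage_rng(config.seed, "decay")
    rows = []
    m0 = truth.genes["mrna_level"].to_numpy()
    k = truth.genes["true_decay_rate"].to_numpy()
    for rep in range(1, config.n_replicates + 1):
        for t in config.timepoints:
            noise = (rng.lognormal(0.0, config.noise_sd, size=len(m0))
                     if config.noise_sd > 0 else np.ones_like(m0))
            rows.append(pd.DataFrame(dict(
                gene_id=truth.genes["gene_id"], replicate=rep, time=t,
                fpkm=m0 * np.exp(-k * t) * noise,
            )))
    return pd.concat(rows, ignore_index=True)


def simulate_ribo_seq(truth: SimTruth, config: SimConfig | None = None,
                      condition: str = "wt"):
    """Footprint count table + footprint 5'-position list with 3-nt periodicity.

    Counts are Poisson with mean proportional to mRNA level x TE (wild-type
    or mutant TE per ``condition``); footprint 5' ends sit at a uniform
    codon with frame 0 at probability ``frame0_fraction`` (remaining mass
    split between frames 1 and 2).
    """
    config = config or truth.config
    if condition not in ("wt", "mut"):
        raise ValueError("condition must be 'wt' or 'mut'")
    te_col = "true_te" if condition == "wt" else "true_te_mut"
    rng = stage_rng(config.seed, f"ribo_{condition}")
    # ribosome density is uniform per codon, so footprints scale with
    # mRNA level x TE x CDS length (RPKM later divides the length back out)
    cds_len = (truth.genes["cds_end"] - truth.genes["cds_start"]).to_numpy()
    weight = truth.genes["mrna_level"] * truth.genes[te_col] * cds_len
    lam = config.ribo_reads_per_gene_mean * weight / weight.mean()
    counts = rng.poisson(lam.to_numpy())
    count_table = pd.DataFrame(dict(gene_id=truth.genes["gene_id"], count=counts))

    gene_rep = np.repeat(np.arange(len(counts)), counts)
    cds_start = truth.genes["cds_start"].to_numpy()[gene_rep]
    n_codons = ((truth.genes["cds_end"] - truth.genes["cds_start"]) // 3).to_numpy()[gene_rep]
    codon = rng.integers(0, n_codons)
    f0 = config.frame0_fraction
    frame = rng.choice(3, size=len(gene_rep), p=[f0, (1 - f0) / 2, (1 - f0) / 2])
    positions = pd.DataFrame(dict(
        gene_id=truth.genes["gene_id"].to_numpy()[gene_rep],
        position=cds_start + 3 * codon + frame,
    ))
    return count_table, positions


def simulate_paralog_pairs(truth: SimTruth, config: SimConfig | None = None,
                           n_pairs: int | None = None,
                           min_g_offset: float | None = None) -> pd.DataFrame:
    """Disjoint gene pairs whose G-insertion rates differ by >= min_g_offset.

    Within a pair the low-G member, having larger expected capacity, has
    the higher binding affinity under the coupling model; pairs with equal
    rates are always rejected.
    """
    config = config or truth.config
    offset = config.paralog_min_g_offset if min_g_offset is None else min_g_offset
    if n_pairs is None:
        n_pairs = len(truth.genes) // 4
    rng = stage_rng(config.seed, "paralogs")
    order = rng.permutation(len(truth.genes))
    g = truth.genes
    rows = []
    it = iter(order)
    for a, b in zip(it, it):
        ga, gb = g["g_insertion_rate"].iat[a], g["g_insertion_rate"].iat[b]
        if ga == gb or abs(ga - gb) < offset:
            continue  # rejected: members must differ in G rate
        low, high = (a, b) if ga < gb else (b, a)
        # tail-length differences can occasionally invert the capacity
        # ordering; keep only pairs where the G-rate/affinity coupling holds
        if not g["binding_affinity"].iat[low] > g["binding_affinity"].iat[high]:
            continue
        rows.append(dict(
            pair_id=f"P{len(rows) + 1:05d}",
            gene_low_g=g["gene_id"].iat[low], gene_high_g=g["gene_id"].iat[high],
            g_rate_low=g["g_insertion_rate"].iat[low],
            g_rate_high=g["g_insertion_rate"].iat[high],
            affinity_low_g=g["binding_affinity"].iat[low],
            affinity_high_g=g["binding_affinity"].iat[high],
        ))
        if len(rows) >= n_pairs:
            break
    return pd.DataFrame(rows, columns=[
        "pair_id", "gene_low_g", "gene_high_g", "g_rate_low", "g_rate_high",
        "affinity_low_g", "affinity_high_g"])


def simulate_proteome(truth: SimTruth, config: SimConfig | None = None,
                      noise_sd: float = 0.2) -> pd.DataFrame:
    """Protein abundance table: protein = mRNA level x TE x lognormal noise."""
    config = config or truth.config
    rng = stage_rng(config.seed, "proteome")
    noise = (rng.lognormal(0.0, noise_sd, size=len(truth.genes))
             if noise_sd > 0 else np.ones(len(truth.genes)))
    return pd.DataFrame(dict(
        gene_id=truth.genes["gene_id"],
        protein=truth.genes["mrna_level"].to_numpy()
        * truth.genes["true_te"].to_numpy() * noise,
    ))
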