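"""Generator properties: determinism, structural guarantees, and
distributional sanity against the configured parameters."""

import dataclasses
import io as _io

import numpy as np
import pandas as pd
import pytest

from polyabind import synthetic as syn
from polyabind.io import stage_rng, write_fasta
from polyabind.tails import a_tract_decomposition, pab_capacity


def fasta_bytes(transcripts) -> bytes:
    buf = _io.StringIO()
    for g, s in transcripts.items():
        buf.write(f">{g}\n{s}\n")
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# configuration validation


def test_config_rejects_bad_probability():
    with pytest.raises(ValueError, match="probability"):
        syn.SimConfig(n_genes=5, zero_g_gene_fraction=1.5)


def test_config_rejects_unordered_range():
    with pytest.raises(ValueError, match="ordered"):
        syn.SimConfig(n_genes=5, g_rate_range=(0.3, 0.1))


def test_config_rejects_short_reads():
    with pytest.raises(ValueError, match="read_length"):
        syn.SimConfig(n_genes=5, read_length=20)


# ---------------------------------------------------------------------------
# transcriptome


def test_transcriptome_structure(small_truth, small_config):
    ann = small_truth.genes
    assert len(ann) == small_config.n_genes
    assert ann["gene_id"].is_unique
    ends = {s[-30:] for s in small_truth.transcripts.values()}
    assert len(ends) == small_config.n_genes  # distinct 3'-terminal 30-mers
    cds_len = ann["cds_end"] - ann["cds_start"]
    assert (cds_len % 3 == 0).all()
    assert (cds_len > 0).all()
    for gid, seq in small_truth.transcripts.items():
        row = ann[ann.gene_id == gid].iloc[0]
        assert 0 <= row.cds_start < row.cds_end <= len(seq)
        assert seq[-1] in "CT"


def test_transcriptome_deterministic(small_config):
    a = syn.generate_truth(small_config)
    b = syn.generate_truth(small_config)
    assert fasta_bytes(a.transcripts) == fasta_bytes(b.transcripts)
    pd.testing.assert_frame_equal(a.genes, b.genes)


def test_single_gene_transcriptome():
    ann, transcripts = syn.generate_transcriptome(syn.SimConfig(n_genes=1, seed=5))
    assert len(ann) == 1 and len(transcripts) == 1


def test_truth_invariants(small_truth):
    g = small_truth.genes
    assert (g["binding_affinity"] > 0).all()
    assert (g["true_decay_rate"] > 0).all()
    assert (g["true_te"] > 0).all()
    assert (g["mrna_level"] > 0).all()
    zero_frac = (g["g_insertion_rate"] == 0).mean()
    assert 0.4 < zero_frac < 0.9  # around the configured 0.66 at n=60


# ---------------------------------------------------------------------------
# tails


def test_simulate_tail_degenerate(rng):
    assert set(syn.simulate_tail(0.0, 30, 5, rng)) == {"A"}
    assert syn.simulate_tail(1.0, 5, 0, rng) == "GGGGG"


def test_simulate_tail_g_fraction(rng):
    """Empirical G fraction over ~1e5 bases within 3 SE of the rate."""
    rate = 0.1
    tails = [syn.simulate_tail(rate, 50, 10, rng) for _ in range(2000)]
    total = sum(len(t) for t in tails)
    g = sum(t.count("G") for t in tails)
    se = np.sqrt(rate * (1 - rate) / total)
    assert abs(g / total - rate) < 3 * se


def test_expected_capacity_matches_monte_carlo(rng):
    """Closed-form expected capacity vs brute-force simulated tails."""
    for g_rate in (0.0, 0.03, 0.15):
        analytic = syn.expected_capacity(g_rate, 50, 10)
        caps = [
            pab_capacity(a_tract_decomposition(syn.simulate_tail(g_rate, 50, 10, rng)))
            for _ in range(4000)
        ]
        assert analytic == pytest.approx(np.mean(caps), abs=3 * np.std(caps) / np.sqrt(len(caps)) + 1e-9)


# ---------------------------------------------------------------------------
# poly(A)-seq


def test_polya_error_free_reads_contain_true_tail(small_truth):
    reads, truth = syn.simulate_polya_seq(small_truth, seq_error_rate=0.0)
    by_id = {r.read_id: r for r in reads}
    for row in truth.sample(n=200, random_state=0).itertuples():
        assert row.true_tail in by_id[row.read_id].seq


def test_polya_deterministic(small_truth):
    r1, t1 = syn.simulate_polya_seq(small_truth)
    r2, t2 = syn.simulate_polya_seq(small_truth)
    assert [(r.read_id, r.seq, r.qual) for r in r1] == [
        (r.read_id, r.seq, r.qual) for r in r2
    ]
    pd.testing.assert_frame_equal(t1, t2)


def test_polya_read_ids_unique_and_conserved(small_truth):
    reads, truth = syn.simulate_polya_seq(small_truth)
    ids = [r.read_id for r in reads]
    assert len(ids) == len(set(ids))
    assert sorted(ids) == sorted(truth["read_id"])  # conservation


def test_polya_truncation_model_consistent(small_truth):
    """Reads flagged with a full adaptor in the truth table really end with it."""
    reads, truth = syn.simulate_polya_seq(small_truth, seq_error_rate=0.0)
    by_id = {r.read_id: r for r in reads}
    adaptor = small_truth.config.adaptor
    full = truth["adaptor_bases"] == len(adaptor)
    assert 0.5 < full.mean() <= 1.0  # most reads keep the whole adaptor
    for row in truth[full].sample(n=100, random_state=0).itertuples():
        assert by_id[row.read_id].seq.endswith(adaptor)
    for row in truth[~full].head(50).itertuples():
        seq = by_id[row.read_id].seq
        assert len(seq) == small_truth.config.read_length  # truncated at read end


# ---------------------------------------------------------------------------
# CLIP


def test_clip_zero_affinity_gene_gets_no_reads(small_truth):
    truth = syn.SimTruth(
        config=small_truth.config,
        genes=small_truth.genes.copy(),
        transcripts=small_truth.transcripts,
    )
    truth.genes.loc[0, "binding_affinity"] = 0.0
    gene0 = truth.genes.loc[0, "gene_id"]
    _, counts = syn.simulate_clip_library(truth, emit_reads=False)
    assert counts.loc[counts.gene_id == gene0, "unique_molecules"].iloc[0] == 0


def test_clip_duplicate_rate(small_config, small_truth):
    cfg = dataclasses.replace(small_config, clip_duplicate_rate=0.5)
    reads, _ = syn.simulate_clip_library(small_truth, cfg)
    seqs = [r.seq for r in reads]
    dup_frac = 1 - len(set(seqs)) / len(seqs)
    # geometric re-emission: expected duplicate fraction = configured rate
    assert dup_frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(seqs) / 2))


def test_clip_count_ratio_follows_affinity():
    """Two genes, equal mRNA, affinity 1 vs 2 -> Poisson count ratio 2."""
    cfg = syn.SimConfig(n_genes=2, seed=9, clip_reads_per_gene_mean=5000)
    truth = syn.generate_truth(cfg)
    truth.genes["mrna_level"] = 10.0
    truth.genes["binding_affinity"] = [1.0, 2.0]
    _, counts = syn.simulate_clip_library(truth, cfg, emit_reads=False)
    c1, c2 = counts["unique_molecules"]
    se = np.sqrt(1 / c1 + 1 / c2) * (c2 / c1)
    assert c2 / c1 == pytest.approx(2.0, abs=3 * se)


# ---------------------------------------------------------------------------
# decay course


def test_decay_noiseless_is_exact_exponential(small_truth):
    cfg = dataclasses.replace(small_truth.config, noise_sd=0.0, n_replicates=1)
    course = syn.simulate_decay_course(small_truth, cfg)
    g = small_truth.genes.iloc[7]
    sub = course[course.gene_id == g.gene_id].sort_values("time")
    expected = g.mrna_level * np.exp(-g.true_decay_rate * sub["time"].to_numpy())
    np.testing.assert_allclose(sub["fpkm"].to_numpy(), expected, rtol=1e-12)


def test_decay_zero_rate_constant_series(small_truth):
    truth = syn.SimTruth(
        config=small_truth.config, genes=small_truth.genes.copy(),
        transcripts=small_truth.transcripts,
    )
    truth.genes["true_decay_rate"] = 0.0
    cfg = dataclasses.replace(truth.config, noise_sd=0.0, n_replicates=1)
    course = syn.simulate_decay_course(truth, cfg)
    for _, sub in course.groupby("gene_id"):
        assert sub["fpkm"].nunique() == 1


def test_decay_replicate_cv_matches_noise():
    cfg = syn.SimConfig(n_genes=300, seed=13, noise_sd=0.1, n_replicates=3)
    truth = syn.generate_truth(cfg)
    course = syn.simulate_decay_course(truth, cfg)
    t0 = course[course.time == 0]
    cv = t0.groupby("gene_id")["fpkm"].apply(lambda v: v.std(ddof=1) / v.mean())
    # lognormal sigma=0.1 -> CV = sqrt(exp(sigma^2) - 1) ~ 0.1003
    assert cv.mean() == pytest.approx(0.1, abs=0.02)


# ---------------------------------------------------------------------------
# ribo-seq


def test_ribo_pure_frame0(small_truth):
    cfg = dataclasses.replace(small_truth.config, frame0_fraction=1.0)
    _, positions = syn.simulate_ribo_seq(small_truth, cfg)
    starts = small_truth.genes.set_index("gene_id")["cds_start"]
    frames = (positions["position"] - positions["gene_id"].map(starts)) % 3
    assert (frames == 0).all()


def test_ribo_counts_scale_with_te():
    cfg = syn.SimConfig(n_genes=40, seed=21, ribo_reads_per_gene_mean=2000)
    truth = syn.generate_truth(cfg)
    doubled = syn.SimTruth(config=cfg, genes=truth.genes.copy(),
                           transcripts=truth.transcripts)
    doubled.genes["true_te"] = 2 * truth.genes["true_te"]
    c1, _ = syn.simulate_ribo_seq(truth, cfg)
    c2, _ = syn.simulate_ribo_seq(doubled, cfg)
    # uniform doubling renormalizes away: per-gene expected counts unchanged
    ratio = c2["count"].sum() / c1["count"].sum()
    assert ratio == pytest.approx(1.0, abs=0.02)
    # non-uniform doubling shifts mass onto the doubled gene
    one = syn.SimTruth(config=cfg, genes=truth.genes.copy(),
                       transcripts=truth.transcripts)
    one.genes.loc[0, "true_te"] *= 2
    c3, _ = syn.simulate_ribo_seq(one, cfg)
    w = truth.genes["mrna_level"] * truth.genes["true_te"] * (
        truth.genes["cds_end"] - truth.genes["cds_start"])
    w3 = w.copy(); w3.iloc[0] *= 2
    expect = 2 * (w.mean() / w3.mean())
    got = c3["count"].iloc[0] / c1["count"].iloc[0]
    assert got == pytest.approx(expect, abs=3 / np.sqrt(min(c1["count"].iloc[0], 1e9)) * expect)


def test_ribo_frame_fraction(small_truth):
    _, positions = syn.simulate_ribo_seq(small_truth)
    starts = small_truth.genes.set_index("gene_id")["cds_start"]
    frames = (positions["position"] - positions["gene_id"].map(starts)) % 3
    f0 = (frames == 0).mean()
    n = len(frames)
    se = np.sqrt(0.9 * 0.1 / n)
    assert abs(f0 - 0.9) < 3 * se


# ---------------------------------------------------------------------------
# paralogs and proteome


def test_paralog_pairs_reproducible_and_coupled(small_truth):
    pairs = syn.simulate_paralog_pairs(small_truth, n_pairs=10)
    pairs2 = syn.simulate_paralog_pairs(small_truth, n_pairs=10)
    pd.testing.assert_frame_equal(pairs, pairs2)
    assert (pairs["g_rate_low"] < pairs["g_rate_high"]).all()
    # coupling: the low-G member always binds better, pre-noise
    assert (pairs["affinity_low_g"] > pairs["affinity_high_g"]).all()


def test_paralog_equal_rate_pairs_rejected(small_truth):
    truth = syn.SimTruth(config=small_truth.config, genes=small_truth.genes.copy(),
                         transcripts=small_truth.transcripts)
    truth.genes["g_insertion_rate"] = 0.05  # all equal -> nothing to pair
    pairs = syn.simulate_paralog_pairs(truth, min_g_offset=0.0)
    assert pairs.empty


def test_proteome_noise_free_identity(small_truth):
    prot = syn.simulate_proteome(small_truth, noise_sd=0.0)
    ratio = prot["protein"].to_numpy() / small_truth.genes["mrna_level"].to_numpy()
    np.testing.assert_allclose(ratio, small_truth.genes["true_te"].to_numpy(), rtol=1e-12)


def test_proteome_recovers_te_ranking(default_truth):
    from scipy.stats import spearmanr

    prot = syn.simulate_proteome(default_truth, noise_sd=0.2)
    rate = prot["protein"] / default_truth.genes["mrna_level"].to_numpy()
    rho = spearmanr(rate, default_truth.genes["true_te"]).statistic
    assert rho > 0.9


# ---------------------------------------------------------------------------
# cross-stage independence


def test_stage_streams_are_independent(small_config):
    a = stage_rng(small_config.seed, "polya_seq").random(5)
    b = stage_rng(small_config.seed, "clip_seq").random(5)
    assert not np.allclose(a, b)
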