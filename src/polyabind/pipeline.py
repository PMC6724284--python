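"""End-to-end run orchestration: simulate -> call tails -> CLIP BE ->
decay -> TE -> statistics, with every stage seeded from one global seed.

A run writes all stage TSVs plus a JSON statistics summary into a run
directory, together with a ``run_meta.json`` stamping the configuration
hash, the seed and the emitted files.  Re-running the same configuration
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clip, dynamics, stats, synthetic, tails
from .io import config_hash, write_fasta, write_fastq, write_table


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``sim`` holds overrides for :class:`polyabind.synthetic.SimConfig`
    fields; unknown keys anywhere are rejected at load time.
    """

    seed: int = 42
    out_dir: str = "polyabind_run"
    sim: dict = field(default_factory=dict)
    min_insert: int = 18
    min_g_quality: int = 20
    min_fpkm: float = 1.0
    te_floors: tuple[float, float] = (0.5, 1.0)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        # validate sim overrides eagerly
        cfg.sim_config()
        return cfg

    def sim_config(self) -> synthetic.SimConfig:
        return synthetic.SimConfig(seed=self.seed, **self.sim)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - reported with stage name
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    emitted: list[str] = []

    def save_table(df: pd.DataFrame, name: str):
        write_table(df, out / name)
        emitted.append(name)

    # --- simulate ----------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        truth = synthetic.generate_truth(sim)
        write_fasta(out / "transcripts.fasta", truth.transcripts)
        emitted.append("transcripts.fasta")
        save_table(truth.genes[["gene_id", "cds_start", "cds_end"]], "annotation.tsv")
        save_table(truth.genes, "truth_genes.tsv")
        return truth

    truth = _simulate()

    # --- poly(A)-seq + tail calling ---------------------------------------
    @_stage("call_tails")
    def _tails():
        reads, read_truth = synthetic.simulate_polya_seq(truth, sim)
        write_fastq(out / "polya.fastq", reads)
        emitted.append("polya.fastq")
        save_table(read_truth, "polya_truth.tsv")
        index = tails.TranscriptIndex(truth.transcripts)
        calls = tails.process_polya_reads(
            reads, index, adaptor=sim.adaptor, prefix_n=sim.prefix_n,
            min_g_quality=config.min_g_quality, min_insert=config.min_insert,
        )
        save_table(calls, "tail_calls.tsv")
        profiles = tails.aggregate_gene_profiles(calls)
        save_table(profiles, "gene_tail_profiles.tsv")
        return calls, profiles, tails.tail_composition_stats(calls)

    calls, profiles, composition = _tails()

    # --- CLIP + binding efficiency ----------------------------------------
    @_stage("clip_be")
    def _clip():
        clip_reads, clip_counts = synthetic.simulate_clip_library(truth, sim)
        write_fastq(out / "clip.fastq", clip_reads)
        emitted.append("clip.fastq")
        save_table(clip_counts, "clip_truth_counts.tsv")
        mrna = synthetic.simulate_expression_table(truth, sim, label="mrna")
        save_table(mrna, "mrna_fpkm.tsv")
        be, positions, oligo = clip.run_clip_pipeline(
            clip_reads, truth.transcripts, mrna, barcode_n=sim.clip_barcode_n,
            min_len=config.min_insert, min_fpkm=config.min_fpkm,
        )
        save_table(be, "binding_efficiency.tsv")
        profile = clip.metagene_profile(positions)
        save_table(pd.DataFrame({"bin": np.arange(len(profile)),
                                 "density": profile}), "metagene_profile.tsv")
        return be, mrna, oligo

    be, mrna, oligo = _clip()

    # --- decay -------------------------------------------------------------
    @_stage("decay")
    def _decay():
        course = synthetic.simulate_decay_course(truth, sim)
        save_table(course, "decay_course.tsv")
        fits = dynamics.fit_decay_table(course)
        save_table(fits, "decay_fits.tsv")
        return fits

    decay_fits = _decay()

    # --- translational efficiency ------------------------------------------
    @_stage("te")
    def _te():
        cds_len = truth.cds_lengths()
        te_tables = {}
        for cond in ("wt", "mut"):
            counts, positions = synthetic.simulate_ribo_seq(truth, sim, condition=cond)
            save_table(counts, f"ribo_counts_{cond}.tsv")
            rpkm = dynamics.compute_rpkm(counts, cds_len)
            te_tables[cond] = dynamics.compute_te(rpkm, mrna, floors=config.te_floors)
            save_table(te_tables[cond], f"te_{cond}.tsv")
            if cond == "wt":
                period = dynamics.periodicity_score(
                    positions, truth.genes.set_index("gene_id")["cds_start"])
        reduced = dynamics.reduced_te_set(te_tables["wt"], te_tables["mut"])
        save_table(reduced, "reduced_te.tsv")
        return te_tables, reduced, period

    te_tables, reduced, periodicity = _te()

    # --- proteome -----------------------------------------------------------
    @_stage("proteome")
    def _proteome():
        protein = synthetic.simulate_proteome(truth, sim)
        save_table(protein, "proteome.tsv")
        synth = dynamics.protein_synthesis_rate(protein, mrna)
        save_table(synth, "protein_synthesis_rate.tsv")
        return synth

    _proteome()

    # --- statistics ----------------------------------------------------------
    @_stage("stats")
    def _stats():
        gene = profiles.merge(
            be[["gene_id", "binding_efficiency"]], on="gene_id", how="inner"
        ).merge(
            te_tables["wt"][["gene_id", "te"]], on="gene_id", how="left"
        ).merge(
            decay_fits[["gene_id", "rate"]], on="gene_id", how="left"
        ).dropna(subset=["binding_efficiency"])

        assoc = stats.decile_association(gene["g_percent"], gene["binding_efficiency"])
        save_table(assoc.bins, "g_percent_decile_bins.tsv")

        te_ok = gene.dropna(subset=["te"])
        from scipy.stats import spearmanr
        rho_te, p_te = spearmanr(te_ok["binding_efficiency"], te_ok["te"])
        decay_ok = gene.dropna(subset=["rate"])
        rho_decay, p_decay = spearmanr(decay_ok["binding_efficiency"], decay_ok["rate"])

        pairs = synthetic.simulate_paralog_pairs(truth, sim)
        save_table(pairs, "paralog_pairs.tsv")
        be_by_gene = be.set_index("gene_id")["binding_efficiency"]
        pairs_be = pairs.assign(
            be_low=pairs["gene_low_g"].map(be_by_gene),
            be_high=pairs["gene_high_g"].map(be_by_gene),
        ).dropna(subset=["be_low", "be_high"])
        try:
            _, paralog_p, n_pairs = stats.paired_paralog_test(
                pairs_be["be_low"], pairs_be["be_high"])
        except ValueError:
            paralog_p, n_pairs = np.nan, len(pairs_be)

        ladder_data = gene.rename(
            columns={"median_tail_length": "tail_length"}
        ).merge(mrna.rename(columns={"fpkm": "mrna_level"}), on="gene_id")
        ladder = stats.aic_ladder(ladder_data)
        save_table(ladder, "aic_ladder.tsv")

        flagged = reduced.set_index("gene_id")["reduced_te"]
        enrich_genes = profiles.assign(
            exclusive=profiles["frac_exclusive_a"] == 1.0,
            reduced=profiles["gene_id"].map(flagged),
        ).dropna(subset=["reduced"])
        ct = pd.crosstab(enrich_genes["exclusive"], enrich_genes["reduced"])
        if ct.shape == (2, 2):
            # rows: exclusive-A yes/no; cols: reduced-TE yes/no
            table22 = [[int(ct.loc[True, True]), int(ct.loc[True, False])],
                       [int(ct.loc[False, True]), int(ct.loc[False, False])]]
            odds, enrich_p = stats.enrichment_test(table22)
        else:
            odds, enrich_p = np.nan, np.nan

        return dict(
            n_genes=int(sim.n_genes),
            composition={k: (None if isinstance(v, float) and np.isnan(v) else v)
                         for k, v in composition.items()},
            oligo_a_fraction=oligo,
            periodicity_score=periodicity,
            rho_g_percent_vs_be=assoc.rho, p_g_percent_vs_be=assoc.p_value,
            rho_be_vs_te=float(rho_te), p_be_vs_te=float(p_te),
            rho_be_vs_decay=float(rho_decay), p_be_vs_decay=float(p_decay),
            paralog_p=None if np.isnan(paralog_p) else float(paralog_p),
            paralog_n_pairs=int(n_pairs),
            enrichment_odds_ratio=None if np.isnan(odds) else float(odds),
            enrichment_p=None if np.isnan(enrich_p) else float(enrich_p),
            aic=dict(zip(ladder["predictors"], ladder["aic"].round(6))),
        )

    summary = _stats()

    with open(out / "stats_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    emitted.append("stats_summary.json")

    meta = dict(config=config.to_dict(), config_hash=config_hash(config.to_dict()),
                seed=config.seed, files=sorted(emitted))
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return summary
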