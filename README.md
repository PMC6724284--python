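# polyabind

Analysis of mRNA **poly(A)-tail composition** and its consequences for
**poly(A)-binding protein (PAB) occupancy**, mRNA stability, and
translational efficiency — built and tested entirely on a seeded
synthetic-data generator with recorded ground truth.

## The scientific problem

Eukaryotic mRNAs end in a poly(A) tail that cytoplasmic PABs coat. The tail
is not always pure adenosine: guanosines are interspersed at gene-specific
rates, and because one PAB footprint needs ~12 consecutive A's, each G can
cut the tail into A-tracts too short to bind. The package implements the
quantitative chain that connects these observations for a
*tail-sequencing + CLIP-seq + ribo-seq + decay time-course* study design:

- **Tail calling.** A tail-sequencing read is `[3-nt random prefix][3'-UTR
  insert][tail][3' adaptor TGGAATTCTCGGGTGCCAAGG]`. The tail is the longest
  3' suffix of the insert over `{A, G}` with at most 5 interspersed G,
  accepted only if its first 5 bases are A; any G with Phred < 20 rejects
  the read. Per gene: `G% = 100 * (total G) / (total tail length)`, median
  tail length, exclusive-A fraction, and PAB capacity
  `sum(floor(tract / 12))`.
- **Binding efficiency.** CLIP reads are deduplicated (full sequence,
  barcode included), barcode-stripped, 3' A-trimmed, length-filtered
  (>= 18 nt) and assigned to transcripts; per gene
  `BE = CLIP RPM / mRNA FPKM`.
- **Decay rate.** The slope of the OLS regression
  `ln(mRNA_0 / mRNA_t) ~ t` over t = 0, 0.5, 1, 2, 4, 8 h, fitted per
  replicate and averaged; half-life `ln 2 / k`.
- **Translational efficiency.** `TE = ribo RPKM (CDS) / mRNA FPKM` for
  genes with > 0.5 RPKM and > 1 FPKM; footprint frame periodicity as QC.
- **Statistics.** Spearman association of G% with BE (with equal-size rank
  bins for display), a one-sided Wilcoxon signed-rank test on paralog pairs
  differing in G%, an 8-model AIC ladder for TE predictors
  (`AIC = n ln(RSS/n) + 2(k+1)`), Mann-Whitney group comparisons, Fisher's
  exact enrichment of exclusive-A tails in reduced-TE genes, and Mendelian
  segregation tests for a selfed heterozygote with an embryo-lethal class.

Every input is produced by `polyabind.synthetic`, whose ground-truth tables
make exact recovery testable: with error-free reads, 100% of accepted tail
calls equal the generated tails, and measured gene G% matches
truth-derived G% to machine precision.

## Worked example

```python
from polyabind import synthetic as syn, tails, clip, stats

cfg = syn.SimConfig(n_genes=300, seed=1)
truth = syn.generate_truth(cfg)

reads, _ = syn.simulate_polya_seq(truth, cfg)
index = tails.TranscriptIndex(truth.transcripts)
calls = tails.process_polya_reads(reads, index)
profiles = tails.aggregate_gene_profiles(calls)
comp = tails.tail_composition_stats(calls)

_, counts = syn.simulate_clip_library(truth, cfg, emit_reads=False)
mrna = syn.simulate_expression_table(truth, cfg)
cc = counts.rename(columns={"unique_molecules": "clip_reads"})
be = clip.binding_efficiency(clip.compute_rpm(cc[cc.clip_reads > 0]), mrna)

gene = profiles.merge(be[["gene_id", "binding_efficiency"]], on="gene_id")
assoc = stats.decile_association(gene["g_percent"], gene["binding_efficiency"])
```

prints (via the obvious f-strings):

```
tails called: 4936 of 6107 reads
tails with >=1 G: 15.0%  genes with >=1 G: 39.8%
per-gene G% range among G-containing genes: 0.06-15.6%
Spearman rho(G%, binding efficiency) = -0.371  (p = 5.32e-11, n = 293)
```

Reads fail tail calling only for identifiable reasons (adaptor truncated
past recognition, impure tail 5' end, >5 G forcing a truncated and
therefore unmappable call); the negative G%-binding association is the
generator's capacity coupling recovered by the measurement chain.

A shell-first workflow is available through the `polyabind` CLI
(`simulate`, `call-tails`, `clip-be`, `decay`, `te`, `stats ...`, `run`);
`polyabind run --seed 5 --out run_dir` executes the whole chain and writes
every stage table plus `stats_summary.json`, byte-identically for a fixed
seed.

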