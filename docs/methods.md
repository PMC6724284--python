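# Methods

This note documents the models, defaults, numerical choices, and
limitations of `polyabind`. Nothing here states an empirical result beyond
what the test suite and `scripts/acceptance.py` compute.

## Tail model and tail calling

A poly(A) tail is modelled as a string over `{A, G}`: length drawn from a
discretized normal (per-gene median around 50 nt, SD 15 nt, truncated at
1 nt), each base independently G with a gene-specific rate. The normal
shape is the simplest consistent with summarising a gene by its *median*
tail length; i.i.d. G placement matches the aggregate-G% level at which
tails are analysed (no positional structure is claimed). Two thirds of
genes never insert G; the remaining genes draw their per-base G rate
log-uniformly on [0.008, 0.28], so most G-genes are low-G while per-gene
G% spans roughly 0.8–28%.

The caller recovers the tail as the **longest suffix** of the
adaptor-proximal insert over `{A} ∪ allowed_non_A` (default `{G}`)
containing at most `max_non_a = 5` non-A bases; the call is accepted iff
its first `min_lead_a = 5` bases are all A. Longest-suffix is the natural
maximisation of "a stretch of A's at the 3' end" — ties are impossible by
maximality, and the rule is verified against an exhaustive all-suffixes
oracle. The 3'-terminal base of a tail may be non-A (adaptor ligation does
not constrain it); "at least 5 A at the 5' end" is read as *the first five
tail bases are A*. The "up to 5 G" budget counts per base, not per run.
Any G in an accepted tail with Phred < 20 rejects the read; all-A tails
always pass. Adaptor search takes the leftmost suffix-anchored occurrence,
tolerating 1 substitution, and accepts a terminal adaptor prefix of
>= 10 nt (both configurable).

Gene assignment is by unique exact suffix match of the tail-trimmed insert
(>= 18 nt) against transcript 3' ends; ambiguity discards the read. Real
alignment is out of scope, so the generator guarantees distinct 3'-terminal
30-mers.

**A structural consequence worth knowing:** tails carrying more than 5 G
are truncated by the longest-suffix rule, so their trimmed insert retains
tail bases and cannot match any transcript 3' end — such reads leave the
analysis as `unassigned` (or `short_lead_a` when the truncated suffix
starts at a G boundary). This is why, on error-free reads, *accepted and
assigned* calls reproduce the generated tails exactly.

## Synthetic transcriptome

Random-uniform sequences of 300–600 nt; CDS length a multiple of 3 with a
5' UTR of 10–40 nt and a 3' UTR of at least 60 nt. Transcripts end in C or
T: a 3'-terminal A or G would be absorbed into the called tail by the
longest-suffix rule and the true tail boundary would be unidentifiable in
principle. Real 3' ends have no such guarantee — cleavage-site-adjacent
genomic A's are a known ambiguity of real tail-seq that this generator
deliberately removes so that recovery can be tested exactly.

## CLIP / binding efficiency

Per-gene unique CLIP molecules are Poisson with mean proportional to
`mRNA level x binding affinity`, where
`affinity = 1 + slope x E[capacity]` (slope default 1). `E[capacity]` has
the closed form `sum_m (1-p)^(12m) (1 + (L - 12m) p)` averaged over the
tail-length quantile grid (cross-checked against Monte-Carlo tails pushed
through the production capacity function). Each molecule carries a 4-nt
random barcode, a 20–40-nt 3'-UTR body and a 12–30-nt terminal A-tract;
PCR re-emits each molecule Geometric(1 − d) times so the duplicate-read
fraction equals d (default 0.15). Preprocessing order is fixed and tested:
dedup → barcode strip → A-trim → length filter → assign.

BE = CLIP RPM / mRNA FPKM over genes above a 1-FPKM floor (the same floor
the TE computation uses; no BE-specific floor is prescribed anywhere, and
the guard exists to keep ratios finite and stable). BE is invariant to
uniform rescaling of either library. Cross-sample BE comparisons use
Pearson on log10 BE. The default library depth (200 unique molecules per
gene in expectation) keeps read-level simulation fast; the
cross-replicate BE correlation is depth-limited at that setting (~0.87)
and exceeds 0.9 at a depth comparable to real libraries (~10^3 molecules
per gene), which is what the corresponding test simulates via the
counts-only path.

## Decay and translation

FPKM(t) = FPKM(0) · exp(−k t) · LogNormal(0, σ) with σ = 0.1 by default,
independently per time point and replicate; decay rates are drawn
Uniform(0.05, 1.5) h⁻¹ **independently of binding**, so the BE–decay
association is null by construction. The regression of ln(m₀/m_t) on t
keeps an intercept — it absorbs the t = 0 normalisation noise; forcing the
line through the origin would bias the slope whenever m₀ is noisy.
Replicates are fitted separately and slopes averaged (mirroring
"average degradation rate" semantics) rather than pooling points.
Non-positive FPKM values carry no log signal and are dropped; fewer than
3 usable points in every replicate yields a reasoned non-fit.

Ribosome-footprint counts are Poisson with mean proportional to
`mRNA x TE x CDS length` (uniform per-codon density; RPKM divides the
length back out). Footprint 5' ends sit at a uniform codon with frame 0 at
probability 0.9. True TE couples to binding as
`TE ∝ (affinity / mean affinity)^te_coupling x LogNormal(0, 0.4)`
(coupling 1 by default). In the PAB-depleted condition
`TE_mut = TE x exp(−0.5 · affinity / mean affinity)`: genes that bind more
PAB lose more TE, which is what makes the reduced-TE set enriched for
high-BE, exclusive-A genes. TE floors are strict (`> 0.5` RPKM,
`> 1` FPKM).

## Statistics

- G%–BE association: Spearman on unbinned gene values; ten equal-size rank
  bins (ties to the lower bin) are a display summary only.
- Paralog test: the paired comparison is the Wilcoxon signed-rank test
  (the standard paired analogue of a "paired Mann-Whitney U"), one-sided
  for higher BE in the low-G member, zero differences dropped, at least 6
  informative pairs required. Simulated pairs must differ in G rate by a
  minimum offset (0.01) and are kept only when the affinity ordering
  follows the G-rate ordering, so the coupling is exact pre-noise.
- AIC ladder: eight OLS models from null to
  `TE ~ mRNA + tail length + G%`. TE and mRNA level are log10-transformed
  (they span orders of magnitude; linear fits are outlier-dominated —
  a flag disables the transform); tail length and G% enter linearly.
  `AIC = n ln(RSS/n) + 2(k+1)`, verified against an independent Gaussian
  log-likelihood computation; only orderings between models on the same
  response are meaningful, and absolute AIC values are data-dependent and
  not comparable across datasets. Rank-deficient designs are skipped with
  a reason.
- Group comparison: Mann-Whitney U, exact when both groups have <= 8
  observations, tie-corrected normal approximation otherwise. Enrichment:
  Fisher's exact (two-sided by point probability), Haldane-corrected odds
  ratio when a cell is zero. Segregation: exact two-sided binomial test;
  a selfed heterozygote with a lethal homozygous class gives viable
  WT:het = 1:2 and a 25% aborted fraction.
- No multiple-testing correction anywhere: single raw p values are
  reported by design.
- Calibration checks run each test on its own large-sample null (20 pairs;
  50 + 50; 2×2 tables from Binomial(1000, 0.5) margins; Binomial(600, 2/3))
  where the discrete tests' attainable size is near-nominal; at small
  sample sizes Fisher's exact test is intrinsically conservative, which is
  a property of the test, not of this implementation.

## Seeds and determinism

One global seed; every stage draws from a substream keyed by
SHA-256(stage name, seed), so stages are independent, reorderable, and
individually reproducible. Fixed config + seed reproduces every FASTQ,
table, and JSON byte for byte (tested).

## Problem sizes

Full-size checks run at 2000 genes (~20 poly(A) reads/gene, 200 CLIP
molecules/gene, 300 footprints/gene, 6 time points × 3 replicates) — the
scale at which the recovery and association properties are stated. The
AIC-ordering study uses 100 independent 400-gene simulations with mild
(σ = 0.1) measurement noise on expression-scale tables.

## Known limitations

- The generator omits C/U tail contamination by default (an
  `allowed_non_a` flag widens the caller for composition studies), splicing
  and alignment artifacts, paired-end mate structure, UMI chemistry, and
  isoform resolution.
- Binding affinity is a stated monotone (affine) function of expected
  capacity; the real coupling shape is unknown, so only signs and
  orderings of downstream associations are meaningful claims.
- Exact-suffix gene assignment presumes the generator's distinct-3'-end
  guarantee; it is not an aligner and will discard reads from genes with
  shared 3' ends rather than resolve them.
- Passing recovery tests here demonstrates the correctness of the
  measurement chain under the generative assumptions, not the biological
  accuracy of those assumptions on real libraries.
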