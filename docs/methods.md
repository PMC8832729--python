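# Methods

`zdosage` analyses sex-biased gene expression on an avian-style Z chromosome
(ZZ males, ZW females) from long-read transcriptome quantifications, and ships
a generator that produces synthetic datasets with known ground truth for every
analysis it performs.

## Statistical model and analyses

### Normalization

Counts are normalized to counts per million (CPM): each sample's column is
divided by its total and multiplied by a scale constant (default 1e6). Gene
level expression is the sum of its transcripts' counts, summed **before**
normalization. CPM is a *compositional* normalization: if one chromosome
genuinely carries more reads in one sex, CPM redistributes that difference
across all genes (see "Known consequences" below).

### Per-gene sex bias

For one tissue, per-gene bias is `log2(mean_M / mean_F)` of CPM across
replicates; its absolute value is the *amplitude*. Genes are only included
when expressed (mean > 0) in both sexes, and the chromosomes `W`, `31`, `33`
are excluded outright (female-limited or unreliable assemblies in the kind of
genome this models). Genes with amplitude > 5 are flagged as outliers —
these are retained in the table but excluded from all window and
chromosome-level means, since a single 32-fold gene would dominate a window
mean.

### Z:AA dosage test

Within each sex separately, Z-linked gene expression `log2(CPM + 1)` is
compared against autosomal expression with a two-sided Wilcoxon rank-sum
test. Under incomplete dosage compensation the female Z (one copy) sits
significantly below autosomes while the male Z (two copies) does not — that
asymmetric pattern, not a single p-value, is the diagnostic readout.

The rank-sum test has three modes:

- `exact`: tie-aware exact null distribution via dynamic programming over the
  subset sums of doubled mid-ranks (doubling keeps sums integral in the
  presence of `.5` mid-ranks). The two-sided p-value is `min(1, 2 * min-tail)`.
- `normal`: the usual normal approximation with tie correction and continuity
  correction (via `scipy.stats.mannwhitneyu`).
- `auto` (default): exact when the smaller group has ≤ 8 observations,
  normal otherwise. The exact path exists because at such sizes the null
  distribution is coarse and the normal approximation can be off by far more
  than conventional significance margins (measured worst-case deviation 0.088
  at group sizes 2–3, 0.031 at 4–8).

### Regional scan

The Z chromosome is scanned in 3 Mb windows stepped by 1 Mb (half-open,
0-based). A gene belongs to a window when its midpoint falls inside it. The
statistic per window is the mean non-outlier `log2 M:F` (and mean amplitude).
The *top region* is the maximal-statistic window merged with any overlapping
windows whose statistic is within 10% of the maximum; ties resolve to the
leftmost window. The 3 Mb / 1 Mb choice trades gene count per window
(variance) against localization (bias): at the default gene density (~2
genes/Mb) a window holds ~6 genes.

### Alternative splicing

Events are classified from transcript structure alone. For each gene, every
transcript pair sharing terminal exon boundaries is compared by intron chain;
contiguous runs of differing introns form components, each classified as one
of five modes:

- **exon skipping** — one or more exons present in one chain, absent and
  spanned by a single intron in the other;
- **intron retention** — an intron of one chain covered by a single exon of
  the other;
- **alternative 5'/3' splice site** — a shared intron end with a shifted
  donor/acceptor (strand-aware: the labels refer to the transcribed
  direction);
- **mutually exclusive exons** — two adjacent exon sets, each private to one
  chain, spliced around by the other.

Anything else falls back to a `complex` label and is excluded from the
five-mode tallies. Differences confined to terminal exons are transcription
start/termination variation, not splicing, and are never events. Events
detected from multiple transcript pairs at identical coordinates and type are
merged; their inclusion/exclusion transcript sets are unions.

PSI (percent spliced in) for an event in a sample is the CPM of inclusion
isoforms divided by the CPM of inclusion plus exclusion isoforms; it is
undefined (NaN) when the denominator is zero. Sex-differential splicing per
tissue uses the rank-sum test on per-sample PSI with Benjamini–Hochberg
correction across events; an event is *significant* when |ΔPSI| ≥ 0.10 and
FDR < 0.05. Events with fewer than two defined samples per sex are skipped.

### lncRNAs

Candidates must exceed 200 nt, have ≥ 2 exons, and carry a noncoding label
(this tool does not compute coding potential). Classification by position
relative to coding genes: `sense` (same-strand exonic overlap), `antisense`
(opposite-strand overlap), `intronic` (contained in an intron on the same
strand), `lincRNA` (no overlap). Opposite-strand intron containment counts
as antisense-style overlap, resolved by the overlap rules before the
intergenic fallback. Targets are coding genes on the same chromosome with a
gap < 100 kb (overlap = distance 0); the `relation` is up/downstream in the
lncRNA's transcribed direction. Sex bias per lncRNA mirrors the gene-level
definition; expression correlation with targets uses Spearman's ρ (rank,
robust to the lognormal scale) alongside Pearson's r.

### Alternative polyadenylation (APA)

Poly(A)-supported read 3' ends are clustered per gene by transitive closure:
ends within `merge_dist` (default 24 bp, roughly the cleavage imprecision of
the poly(A) machinery) of any member join the cluster. A cluster is a *site*
when supported by ≥ 2 reads; its representative position is the modal end
(smallest on ties). Replicates are pooled within (sex, tissue). Genes are
tallied by site count into categories 1, 2, 3, 4, ≥ 5, and the male vs
female category distributions are compared per tissue with a chi-square test
(low-expectation categories pooled into neighbours).

## The generator

`SimulationConfig` → deterministic dataset. Independent `numpy`
`default_rng([seed, k])` streams (k = 11 structure, 23 expression, 37
poly(A) reads, 41 splicing fixtures) keep the annotation invariant under
changes to downstream draws.

**Structure.** Each chromosome gets `n_genes` genes, one per equal-width
slot, uniformly jittered inside the slot — density is even by construction,
so regional statistics are well defined everywhere. Gene models have 2–8
exons (80–400 bp) and introns (200–1500 bp); isoform counts follow a
configurable distribution. Extra isoforms are built by injecting one of the
five AS modes, recorded in the ground truth with exact coordinates and full
inclusion/exclusion transcript sets. lncRNAs are constructed to a requested
class mix (defaults follow genome-wide observed shares: lincRNA 0.72,
antisense 0.17, intronic 0.08, sense 0.03, renormalized).

**Expression.** Baseline per-gene abundance is lognormal
(`baseline_log_mean` = ln 200, `baseline_log_sd` = 1.0 — a realistic
several-decade dynamic range); isoform weights are Dirichlet. Counts are
negative binomial with dispersion φ = 0.1 (typical for biological replicates;
variance = μ + φμ²). Sample library factors are lognormal
(`library_size_sd` = 0.15). Sex enters as a **female reduction**: males at
baseline, females divided by `z_male_fold` (default 1.75) on Z genes —
modelling one Z copy with partial compensatory up-regulation. A hotspot
(default Z:31–36 Mb) multiplies the male:female fold by `extra_fold` = 1.5.

**Poly(A) ends.** Each coding gene draws 1–5 true sites, spaced ≥ 400 bp
(comfortably above 3× merge distance so recovery is unambiguous); each site
emits Poisson(8) reads per sample jittered ±5 bp.

**What it emulates / what it doesn't.** It reproduces the statistical
signatures the analyses target: Z-wide incomplete compensation, a regional
hotspot, five structurally exact AS modes, positionally defined lncRNA
classes, and clustered poly(A) ends. It does **not** model sequences, read
alignment or mapping ambiguity, transcript-assembly errors, GC or length
bias, batch effects, or any sex difference in splicing/APA (those nulls are
what the calibration tests rely on).

## Numerical choices

- Exact rank-sum via integer-weight DP (doubled midranks), verified against
  full enumeration; `auto` threshold min(n) ≤ 8 chosen from the measured
  normal-approximation error.
- BH correction via `statsmodels` `fdr_bh`.
- CPM pseudocount is 0 for ratios (zeros are pre-filtered) and +1 inside the
  Z:AA log transform (bounded, conventional).
- All outputs are plain TSV with a `#`-comment parameter header;
  `summary.json` is recomputed from the tables alone, and a run is
  fingerprinted by a SHA-256 over its config (excluding the output path) and
  over its table bytes — two runs of one seed are byte-identical.

## Limitations

- CPM compositionality biases *absolute* per-chromosome log-ratios whenever
  the Z truly shifts between sexes: with a fraction *z* of the
  transcriptome on Z at fold *f*, every autosomal gene shifts by
  `-log2(1 - z + z·f) + log2(...)`-style terms. The Z-minus-autosome
  **contrast** is invariant and is the recommended effect-size readout.
- The rank-sum normal approximation is unusable below group size ~9; the
  library refuses to hide this (`auto` switches to exact) but `mode="normal"`
  will happily return coarse answers if forced.
- lncRNA identification requires external noncoding labels; no coding
  potential, conservation, or expression threshold is applied.
- APA site calling has no internal-priming filter and assumes the provided
  ends are already poly(A)-supported.
- Differential splicing treats isoform CPM as exact; quantification
  uncertainty of long reads is not propagated.
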