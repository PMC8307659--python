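# Methods

## The statistical model

The unit of observation is a CpG dinucleotide with methylated/unmethylated
read counts per sample. For two conditions with replicates, the pipeline
applies a per-replicate coverage rule and then pools replicate counts within
each condition: the per-replicate filter (coverage ≥ `min_cov` in **every**
replicate of **both** conditions, default 4) guards against calling sites
supported by a single library, while the 2×2 test table is necessarily
per-condition — pooling is the only construction that yields one
contingency table per site from replicated counts.

The site test is the Pearson chi-squared statistic with one degree of
freedom and **no** Yates continuity correction; an unqualified "chi-squared
test" is taken as plain Pearson, and the choice is fixed for
reproducibility rather than because the correction would change qualitative
behaviour. A table with a zero column marginal (all reads methylated in
both conditions, or none) carries no information about a difference and is
assigned χ² = 0, p = 1 rather than an error. Benjamini–Hochberg adjustment
is applied once, genome-wide, over all tested CpGs (not per chromosome).
Significance thresholds are strict inequalities: q < `fdr_threshold`
(default 0.2) and |Δ| > `min_delta` (default 0.1), with
Δ = pooled level(condition B) − pooled level(condition A), positive =
hyper-methylated in B.

## DMR calling

A DMR is a maximal run of same-direction significant CpGs not interrupted
by any **tested** CpG of another state. Two deliberate conventions shape
"consecutive":

* coverage-filtered CpGs are transparent — consecutiveness can only be
  judged among evaluated sites — but the genomic gap guard still applies;
* `min_cpg` defaults to 2 (a "run" of one CpG is a site, not a region) and
  `max_gap` defaults to 1000 bp so that runs cannot silently span coverage
  deserts; `max_gap=None` restores the literal no-gap-rule reading.

The DMR span is first-to-last member CpG (half-open, end = last position
+ 1), not padded. Member CpGs all satisfy the site thresholds by
construction, so region-level effect size is summarized (mean member Δ,
minimum member q) rather than re-tested.

## Genome-wide shift and hexbin summary

The genome-wide comparison reports unbinned mean methylation per condition
over CpGs passing the coverage rule, and tests the shift with a paired
two-sided t-test of per-bin mean levels across genomic bins (default 1 Mb;
the benchmarks use 100 kb bins on a 10 Mb genome, giving 100 pairs). The
test identity for this comparison is a convention of this package: a paired
t-test over bins is robust to the strong spatial autocorrelation of
methylation that would invalidate a per-CpG paired test, and the bin count
controls its resolution. Identical inputs produce a zero-variance
difference; the result is then flagged degenerate with p = NaN rather than
p = 1. The 2-D histogram of (level_A, level_B) over a 50×50 grid on [0,1]²
is the numeric backing of the usual hexbin figure; its total equals the
number of CpGs passing coverage in both conditions.

## Feature context

Overlap semantics are half-open with ≥ 1 bp intersection; single positions
are length-1 intervals. A DMR overlapping two feature classes counts in
both (category percentages are not forced to be exclusive); an optional
priority mode (promoter > 5′UTR > exon > intron > 3′UTR > intergenic)
yields single-assignment splits. Hyper-proportions #hyper/(#hyper+#hypo)
carry Wilson score intervals, which behave sensibly at extreme counts where
Wald intervals collapse. For chromatin-state profiles the per-state
significance is a paired two-sided t-test across chromosomes of the
per-chromosome hyper fraction versus hypo fraction among the state's tested
CpGs, requiring at least 5 informative chromosomes; with fewer, the p-value
is reported missing. This pairing is again a package convention — the
comparanda behind state-level asterisks in published figures of this kind
are rarely stated.

## The synthetic methylome generator

The generator emulates the structure such an experiment assumes, not any
particular dataset:

* **Genome**: `n_chrom` chromosomes (default one of 10 Mb) carrying CpG
  islands (default 50 × 1 kb) with CpG density 0.1/bp inside islands and
  0.01/bp outside, counts drawn as a binomial process. Dyad overlap is not
  excluded — positions are abstract count anchors, not sequence.
* **Baseline methylation**: bimodal, Beta(1, 9) inside islands (mean 0.1)
  and Beta(6, 1.5) outside (mean 0.8), matching the usual vertebrate
  pattern of unmethylated islands in a ~70–80 % methylated background.
* **Coverage**: negative binomial (default mean 10, dispersion 5) because
  WGBS coverage is overdispersed relative to Poisson; the paper-scale
  benchmarks use mean 20. No coverage distribution is estimated from data.
* **Replicates**: two per condition by default; replicate wobble acts on
  the logit of the methylation level (default sd 0.1), which keeps levels
  in (0,1) without ad-hoc clamping.
* **Spiked DMRs**: disjoint runs of `dmr_n_cpg` consecutive background
  CpGs (a 5-CpG buffer prevents adjacent truth regions from fusing),
  hyper or hypo with programmed |Δ| (default 0.4). The baseline inside a
  spiked region is re-drawn uniformly from the band that lets the full Δ
  be expressed within [0.05, 0.95]: spiking ±0.4 on top of a Beta(6, 1.5)
  draw would be clamped at 1 for most of the background mass and the
  realized effect would be a fraction of the programmed one, making
  "truth" a misnomer for recovery benchmarks. The truth table records the
  programmed Δ, which under this design is also the realized one.
* **Global shift**: an additive offset on condition-B levels (clipped to
  [0,1]); clamping loss is negligible at the default baselines for shifts
  of a few percent.
* **Conversion**: an unmethylated cytosine fails to convert with
  probability 1 − `conversion_efficiency` (default 0.995) and then reads
  as methylated — conversion failure inflates apparent methylation, as in
  real bisulfite chemistry. Over-conversion and oxidative errors are not
  modelled. A fully unmethylated spike-in contig (default 5 kb, standing
  in for the lambda-phage DNA spiked into WGBS libraries) yields the
  conversion-efficiency estimate 1 − pooled methylation.
* **Amplicon reads**: top-strand bisulfite images of a single amplicon
  from offset 0, each CpG methylated independently with its programmed
  probability; constant base quality; no sequencing-error model beyond
  conversion failure.

What passing benchmarks on this generator does **not** show: robustness to
mappability artefacts, strand-specific biases, SNPs segregating with
methylation, copy-number differences between lines, or batch effects —
none of which are simulated.

## Amplicon quantification

The reference is converted in silico (top strand C→T, bottom strand
read-out G→A); CpG cytosines are {C,T} wildcards during ungapped alignment
so methylation state cannot bias placement, while an unconverted non-CpG
cytosine simply counts as a mismatch. Reads exceeding a 10 % mismatch
fraction are discarded and counted. Ties prefer the top strand, then the
leftmost offset. Per CpG, methylation = #C/(#C+#T) (bottom-strand reads
read the dyad's G); CpGs below `min_depth` (default 10) are reported but
flagged and excluded from the mean. Both a depth-weighted and an unweighted
mean across CpGs are reported, since summary "promoter methylation"
percentages in the literature rarely state which was used. Conversion
efficiency is estimated from covered non-CpG cytosines. Indels, paired-end
reads and multi-amplicon designs are out of scope.

## Benchmark calibration choices

The acceptance-style benchmarks in `tests/test_acceptance.py` and
`scripts/acceptance.py` fix their own conditions:

* The **null calibration** run (type-I error of the site test) switches
  replicate wobble off in addition to removing spikes, shift and conversion
  failure: the chi-squared null hypothesis is equal *true* proportions, and
  biological replicate variability is a deliberate violation of that null.
  This was decided from the hypothesis being tested, before measurement.
  Even so, the attained size at pooled ~20 vs ~20 reads is ≈ 0.041 rather
  than 0.050: the Pearson statistic on small discrete tables is
  conservative, and no implementation of the same test changes that.
* The **recovery** benchmarks similarly disable replicate wobble and
  conversion failure so that the programmed truth is exactly the simulated
  contrast. At pooled 40 vs 40 reads and Δ = 0.4 the per-CpG power against
  the BH-corrected threshold (p ≈ 10⁻³ at ~500 true sites among 10⁵ tests)
  is ≈ 0.6–0.8 depending on where the baseline sits, which caps
  region-level sensitivity (≥ 2 adjacent significant CpGs of 5) at roughly
  0.75–0.85; precision is essentially 1 because false runs of length ≥ 2
  are rare at q < 0.2. Sensitivity scales with coverage, not with any
  tunable of the caller.
* Benchmark problem sizes (10 Mb genome ≈ 10⁵ CpGs, 100 spiked regions,
  1000 amplicon reads) are the package's chosen desk scale: large enough
  for stable proportions, small enough to iterate on.

## Degenerate inputs and numerical conventions

Zero-coverage sites are kept at I/O and excluded only by the coverage
filter, so filtering statistics are reportable. Levels at exactly 0 or 1
bypass the logit wobble. BH on an empty vector returns an empty vector.
Proportions over zero events are missing (NaN), never 0. DiffSite tables
are written with fixed column order and 6-decimal floats so identical runs
are byte-identical. All randomness flows from a single seed through one
`numpy` generator consumed in a fixed order; outputs are bitwise
reproducible for a fixed config.

## Known limitations

* The chi-squared path ignores replicate-level overdispersion (a
  beta-binomial site model would absorb it); with two replicates per
  condition this is the conventional trade-off.
* `min_cpg`, `max_gap`, the promoter window (TSS ± 1 kb when no BED is
  supplied) and the state-level test pairing are conventions exposed as
  parameters, not estimates.
* The amplicon matcher is ungapped; indel-containing reads are discarded
  via the mismatch cap rather than salvaged.
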