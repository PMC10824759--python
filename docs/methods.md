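# Methods

## Signal model and coordinate conventions

All coordinates are 0-based, half-open internally; BED is native and GTF
(1-based closed) is converted at the boundary. A `SignalTrack` is a
per-strand sparse map position -> count; nascent-RNA 3' ends mark engaged
polymerase positions and 5' ends mark start positions, each read counted
once at the exact base. bedGraph values may be fractional after
normalization; writers print merged equal-value runs with up to six
significant digits, so integer tracks round-trip losslessly.

Window conventions (constant everywhere): promoter `[TSS, TSS+150)`
half-open in the gene direction; gene body `[TSS+250, TES]` with the TES
inclusive (the upstream description leaves inclusivity open; we close the
interval and document it here). Genes whose TES lies within 250 nt of the
TSS get undefined body fields rather than zeros — a zero body would
otherwise produce infinite pausing indices. Promoter and body windows can
never overlap (150 < 250).

## Normalization

Two spike conventions coexist, as in the underlying experimental designs:

* **RNA-seq:** per-sample size factor `ref_reads / spike_reads`, halved
  for haploid samples, used as a divisor of counts. Halving the divisor
  doubles haploid normalized signal, i.e. converts per-cell units to
  per-genome-copy units; this is the only reading under which
  per-copy-constant genes agree across the ploidy change while
  uncorrected signal differs 2-fold, which is exactly what the test suite
  checks. 4C meiotic cells receive no extra correction.
* **Nascent tracks:** multiplier `spike_min / spike_sample` (lowest-spike
  sample = 1), haloid samples halved, for browser-style track output.
  For count-level nascent DE the equivalent divisor form
  `spike_sample / spike_min` (halved for haploids) is used; spike reads
  are proportional to per-sample depth because spike material is added
  per cell, so these factors remove depth exactly.

For the dosage-compensation statistic the RNA status groups are formed
with spike-only (per-cell) factors while the nascent body fold changes use
ploidy-corrected (per-copy) factors. This pairing is what lets
"unchanged" genes (per-cell RNA preserved across meiosis) reveal their
doubled per-copy transcription; both pathways are exposed if a per-copy
RNA view is wanted instead.

Replicate QC computes Spearman correlations (average ranks on ties, which
are common at low counts) of per-gene sums over the first 150 bp
downstream of each TSS.

## TSS refinement

The 1 kb search window is interpreted as centered: +/-500 nt around the
annotated TSS. A gene is active when pooled, unnormalized 5' reads in the
window reach 8 (inclusive); the TSS then moves to the position of maximal
5' count, ties resolved to the most upstream tied position (strand-aware),
biasing the promoter window to contain the full pause region. Candidate
positions beyond the TES are excluded so a short gene cannot capture a
same-strand neighbour's 5' peak. Refinement is idempotent and never moves
a TSS by more than half the window. TES selection among candidate ends
keeps the candidate with maximal mean RNA-seq coverage over its final
500 nt; single-candidate genes pass through.

## Differential testing

The test is an intentionally transparent negative-binomial Wald test on
normalized counts (counts / size factor):

* log2FC = `log2(meanB + c) - log2(meanA + c)` with pseudocount c = 0.5
  normalized counts, bounding fold changes for zero-containing genes.
* Variance model `Var = mu + alpha mu^2` written in normalized counts, so
  the statistics depend on the data only through them (multiplying one
  sample's counts and factor by the same constant changes nothing).
* Dispersion: per-gene method-of-moments pooled across the two groups,
  then moderated toward the across-gene mean of the raw (unfloored)
  estimates with a prior weight of 100 pseudo-observations, floored at 0.
  Raw MoM from 2-3 replicates is noisy enough to inflate the type-I rate
  to ~0.08 at a nominal 0.05; with moderation the measured null level is
  ~0.051 (2,000 genes x 10 seeds), essentially the floor attainable with
  a normal reference at triplicate depth.
* Wald z = log2FC / se with a delta-method se evaluated at mean + c;
  two-sided normal p; Benjamini-Hochberg over tested genes only. Genes
  with zero counts in both groups are `untested` and excluded from
  downstream lists.
* Status: up if padj < 0.05 and fold > 1.5; down if fold < 1/1.5;
  unchanged otherwise (bulk thresholds; pseudobulk uses padj < 0.01 and
  |shrunken log2FC| >= 1).

Pseudobulk fold changes are shrunk toward zero by empirical-Bayes normal
shrinkage: prior variance = across-gene variance of raw log2FC minus the
mean squared se (clipped at 0); each gene is scaled by
`prior / (prior + se^2)`. An infinite prior returns the raw values. This
is a deliberate, documented surrogate for heavier shrinkage machinery;
divergences from it matter only near the |log2FC| = 1 threshold.

Single-cell QC keeps cells with more than 1000 detected genes and less
than 10% mitochondrial counts (both strict), then genes detected in more
than 15 retained cells. Pseudobulk sums counts over selected cell labels
per sample; its size factors are total-count factors with unit geometric
mean (no spike-ins exist in droplet data).

## Clustering and set statistics

K-means uses 25 restarts at a fixed seed (determinism is required by the
test suite); labels are renumbered by centroid peak stage, then by
descending size, so cluster numbers are a stable presentation order.
Relative expression is each gene's fraction of its maximal stage; all-zero
rows are excluded. Gene-length contrasts use the two-sided Mann-Whitney U
test, exact when the combined sample is at most 20. Divergent pairs
require antisense orientation, TSS distance <= 1 kb and shared membership
in the focal cluster, each lncRNA paired to its nearest qualifying mRNA
(antisense is required; a same-strand neighbour is not a divergent pair).
Representation scores divide each cluster's share of a DE set by its
share of all clustered genes, so 1 = chance; their cluster-size-weighted
mean is exactly 1. Set overlaps use the upper-tail hypergeometric
P(X >= observed).

The PWM scanner computes log-odds scores against a uniform background and
converts them to exact p-values via a dynamic program over achievable
partial score sums; because the scan accumulates columns in the same
order, the float sums match the tabulated distribution exactly, and the
DP provably equals 4^L word enumeration (tested to 1e-12 for L <= 8). At
p <= 0.005 on 100 nt windows a motif-free sequence still matches with
probability ~0.4 (95 offsets x 0.005), so the percent-with-match statistic
has a substantial baseline — true of any fixed-threshold scan, and visible
in the worked example.

## DSB analysis

Promoters need >= 5 nascent reads in SG to enter the analysis; quartiles
are assigned after descending stable sort (ties by gene id), sizes
floor(n/4) with the remainder pushed to the lowest quartiles — at
n = 14,804 exactly 3,701 per quartile. DSB flank sums are strand-agnostic
(+/-500 nt inclusive; breaks carry no strand) while metagene offsets are
strand-aware. Quartile comparisons use the unpaired two-sided rank-sum
test by default — the quartile groups are unpaired — with a paired
signed-rank variant available for genuinely paired inputs.

## Synthetic data: what it emulates, what it does not

Defaults (the conditions every test runs under): 2,000 genes on one 60 Mb
chromosome, 3 stages x 3 replicates, lognormal gene lengths (median 8 kb,
late-program genes halved), biotype mix 80/15/5 coding/lncRNA/other, half
the lncRNAs planted as divergent partners of protein-coding genes. Reads
are Poisson-placed: promoter 3' ends uniform on TSS+20..TSS+60 (inside the
promoter window, outside the body window), 5' ends exactly at the true
TSS, body reads uniform on TSS+250..TES, with a gene-level lognormal
replicate factor (sd 0.10) and per-sample lognormal depth (sd 0.20).
Annotated TSSs are shifted downstream of the truth by a clipped
half-normal (sd 120 nt) to exercise refinement.

Six expression archetypes define per-cell stage profiles; their mix
weights were chosen once so that total per-cell RNA is nearly constant
across stages (< 0.1 log2 residual), because reference/spike size factors
are only valid per-cell normalizers under that condition. Program 5 is
flat across SC->RS: by construction those genes keep per-cell output
through meiosis, i.e. double their per-copy transcription — the planted
dosage compensation (truth value 1.0 log2). Program 4 pauses in SG and
elongates in SC (promoter and body maxima in different stages), the
pause-release cohort. DSB rates follow a Gaussian rank copula on SG pause
strength targeting Spearman rho = 0.44, with reads placed ~100 nt
downstream of the TSS (sd 120); Poisson read noise attenuates the realized
correlation by a few hundredths. Single-cell libraries are lognormal
(median 12,000) over SG-profile expression with a floor so every gene is
detectable; planted failure cells have 10% of the normal library (failing
the >1000-genes rule) or 30% mitochondrial content (failing the <10%
rule), with wide margins so truth-recovery tests are exact. Knockout
genotypes down-shift 60 designated genes by 2 log2; the two knockouts
share half their targets so the overlap statistic has signal.

Not emulated: sequence-level reads and alignment artifacts, multimapping,
isoforms and alternative TESs (beyond the candidate-selection operation),
doublets/ambient RNA, batch effects, and genuine global per-cell RNA
shifts between stages (see the balance note above). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to upstream artifacts.

## Numerical choices and degenerate inputs

Overlapping bedGraph intervals are an error (silent summation would hide
double counting); malformed lines report their line number. Empty DE sets,
empty sequence lists and zero spike reads raise instead of returning
NaN-filled tables. Quartile and k-means tie-breaks are deterministic as
described. Simulation scale keeps every driver and the full test suite in
the minutes range on one CPU; the sizes used are stated above and in
`SimulationParams`.

## Known limitations

The NB Wald test trades DESeq2's dispersion machinery for transparency;
its power at marginal effects is lower and its shrinkage cruder. The
ref/spike RNA factor convention assumes comparable total per-cell RNA
across samples (see Normalization); the spike-read convention used for
nascent data does not need this. The PWM scanner is exact but enumerates
achievable score sums, which is exponential in the worst case — intended
for short core-promoter motifs (L <= ~12).
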