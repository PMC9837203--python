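# Methods

This note records the models, conventions and numerical choices behind
`cyclechrom`, in the order the pipeline runs them.

## Coordinates, tracks and normalization

All genomic coordinates are 0-based half-open (BED) internally; BED
conventions are preserved on write. Signal tracks are fixed 10-bp bins. A
raw track's bin value is the *fragment-coverage count* — the number of
sequenced fragments overlapping the bin — while `library_size` is the
number of reads. Normalization is `signal·1e6/reads_signal −
input·1e6/reads_input` per bin, i.e. RPM-scaled coverage minus the matched
input, which reproduces the behaviour of coverage tools that scale extended
reads per million mapped reads. Normalized values may be negative; they are
floored at zero only where a logarithm is taken (fold changes), never in
stored tracks.

Strand convention: the promoter window of a plus-strand gene at TSS t is
[t−500, t+1500); for a minus-strand gene it is [t−1500, t+500), the
half-open reflection of the plus window. With this pairing, reversing every
chromosome and flipping strands leaves every per-gene quantity unchanged
bit for bit on the 10-bp grid, which the tests exercise directly. Profile
matrices use the same reflection and reverse the columns of minus-strand
genes so all rows read 5'→3'.

Percentile trimming for heatmap display winsorizes to the 5th/95th
percentiles (linear interpolation between order statistics) computed
*jointly* over all matrices displayed together, so phases share one colour
scale. Re-trimming an already-trimmed matrix is defined as a no-op:
winsorized data have probability mass sitting exactly on the clip bounds,
so recomputing interpolated percentiles would creep inward.

## Phase comparison statistics

One-way ANOVA treats phases as groups and per-gene promoter means as
observations; zero total variance is defined as F = 0, p = 1. Mann–Whitney
U is two-sided, with the exact null computed by full enumeration of all
C(n₁+n₂, n₁) group assignments of the pooled values when both groups have
≤ 8 observations (correct under ties), and the tie-corrected normal
approximation otherwise. Promoter fold changes use pseudocount 0.5 RPM
after flooring negative means at zero; the pseudocount compresses large
ratios slightly (visible as ≈0.04 log₂ shortfall at a true three-fold
effect of ~13 RPM), which is why the recovery tolerance is ±0.15 log₂
units.

## Target classes

A promoter is a target when any peak overlaps its window by ≥ 1 bp
(half-open, so an abutting peak does not overlap); per-factor sets are
unions over phases. vPRC1/cPRC1/PRC2 promoters require all four of RING1B,
RYBP, CBX7 and EZH2; vPRC1-only promoters carry RING1B and RYBP but
neither CBX7 nor EZH2; intermediate combinations belong to neither class,
making the two classes disjoint by construction. The same window is used
for quantification and classification so the two stay congruent;
it is overridable in the pipeline config. Overlap percentages report the
raw fraction, the half-up rounding and a truncated one-decimal display
value, because printed percentages in this field are commonly truncated
(93.86% displays as 93.8%). High-confidence bivalent promoters are always
an input list, never recomputed.

## Capture-C quantification

normCounts = raw · nprom · 100,000 / cov, with cov the total read count at
captured promoters in the sample and nprom the number of captured
promoters; the value is invariant to joint rescaling of raw counts and cov.
Interaction calling takes fragments with score ≥ 5 (strictly `>=`) that
overlap an accessible region, groups maximal runs of consecutive fragments
(gap tolerance 0, overridable), and excludes the viewpoint's own fragment.
The summit is the fragment of maximal G2 normCounts in the run, ties going
to the viewpoint-proximal fragment. Metaprofiles divide every condition's
window values by the interaction's G2 summit normCounts — so position 0 of
the G2 profile is exactly 1 for each retained interaction — and flip
offsets so positive positions point toward the viewpoint (promoter-
proximal) and negative away (distal). Positions beyond chromosome ends are
excluded from per-position means rather than zero-filled; interactions
whose G2 summit value is non-positive are dropped with a logged warning.
Per-position values are accumulated in sorted order before averaging, so
the profile is independent of interaction order and mirror-image inputs
reproduce it exactly.

Distance-matched controls mirror the summit about the viewpoint
(control = viewpoint − side·distance, an involution), keep the
*interaction's* G2-summit denominator so control and interaction curves
share a scale, and flip with the control's own geometry so proximal still
points at the viewpoint. Control windows falling off-chromosome are
dropped and logged. Group comparisons are two-sided Mann–Whitney on
per-interaction summed normCounts over the run (controls use the mirrored
window of the same width).

## Expression analyses

Nascent RPM is the promoter-window (TSS→+3 kb) count per million library
reads; the synthetic generator emits window counts directly, so the RPM
operation is a per-matrix scaling. Box statistics use linearly interpolated
quartiles and 1.5×IQR whiskers (the most extreme values inside the fence).
MA fractions count FC > 1.2 and FC < 1/1.2 strictly, compared on the
fold-change scale so a gene exactly at the threshold is excluded; the DE
filter likewise uses strict |FC| > 2 and FDR < 0.05, unioned over
contrasts.

TMM normalization follows the trimmed mean of M-values recipe: reference =
sample whose library-scaled 75th-percentile count is closest to the mean of
those quantiles; genes positive in both libraries contribute M (log ratio)
and A (log abundance); 30% of M and 5% of A are trimmed two-sided; the
factor is the mean of remaining M values weighted by inverse delta-method
binomial variances, and factors are rescaled to geometric mean 1. Factors
multiply library sizes (a library that is exactly 2× the reference per gene
gets factor 1; the doubling is absorbed by the library size). The
implementation is cross-checked in the test suite against edgeR's
`calcNormFactors` via Rscript.

Clustering operates on log₂((x+1)/geomean(x+1)) of TMM-normalized values,
with distance 1 − Pearson correlation between gene rows and average
linkage. The mechanical operation (`hclust_genes`) cuts into k clusters
labelled by decreasing size; the RA analysis wrapper (`ra_cluster_labels`)
adds two conventions that the mechanical cut lacks: the tree is cut at
increasing k until the requested number of clusters each hold ≥ 5% of the
genes (stray outlier genes — e.g. false positives of the DE filter, which
otherwise capture a cluster slot at a fixed-k cut — are reassigned to the
nearest major centroid by Euclidean distance), and clusters are named by
their response rather than size: II is the cluster with the strongest
IAA-over-UNT derepression at 6 h, I the more RA-induced and III the
RA-repressed of the rest. Cluster II is sub-cut the same robust way; II-A
is the sub-cluster with the stronger G1-over-G2 preference under UNT.
Constant (zero-variance) rows, where correlation is undefined, are assigned
to the nearest cluster by Euclidean distance and logged.

Preranked GSEA orders genes by decreasing score (ties broken by gene id),
increments the running sum by |score|¹/Σ_hits|score|¹ at hits and
decrements by 1/(N−m) at misses; ES is the signed maximum deviation (exact
± ties resolve positive). The null permutes gene labels: sampled with the
caller's seed, or enumerated exhaustively when C(N, m) fits within the
permutation budget, making small-universe results exact. NES divides ES by
the mean |null ES| of matching sign; nominal p is the one-sided same-sign
tail with +1 smoothing (p = 1 when no null shares the sign, since that
tail is uninformative); FDR across gene sets is Benjamini–Hochberg.

## Synthetic-data generator

The generator encodes the study conditions as defaults and is not meant to
be tuned per analysis. All randomness flows from one integer seed through
named child streams (one per output), so every product is a pure function
of its config.

*Genome and genes.* Two 7.68-Mb chromosomes, 600 genes in distinct 25-kb
slots with bin-aligned TSSs, random strand. Genes split 25% vPRC1/cPRC1/
PRC2 ("vcp"), 25% vPRC1-only, 50% unbound.

*ChIP.* Occupancy is a triangular kernel of half-width 1 kb centred on the
TSS (unit mass over bins). Per bound promoter, G1 occupancy is 150 reads;
G2 multiplies by the factor's phase ratio (RING1B 1.0; RYBP, CBX7,
H2AK119ub1 3.0; EZH2 constant) and S is the geometric midpoint — chosen
because the S-phase signal sits between G1 and G2 in this system. Bin
counts are Poisson at coverage scale (fragment length 200 bp / bin 10 bp =
20× the read rate) and each library's expected read total equals `depth`
(1e6), the background absorbing what occupancy does not use — equal-depth
sequencing, which keeps RPM comparable across phases. Inputs are
background-only libraries of the same depth. Occupancy is constant across
bound genes so that, under a flat phase ratio, per-gene promoter means are
i.i.d. across phases and the ANOVA null calibration is meaningful. Peaks
are emitted at true target promoters (±1 kb).

*Nascent RNA.* Negative binomial (dispersion 0.1) window counts. Unbound
genes: mean 1500, phase- and genotype-invariant (they dominate the
libraries, keeping RPM composition bias ≈ 0.03 log₂ units, well inside the
±0.15 recovery band; polycomb targets are lowly expressed in reality,
which this mimics). Targets: mean 100 in G1, divided by the configured
G1/G2 ratio (2.0) in G2, geometric midpoint in S; knockout multiplies
S/G2 means by the derepression map (G1 1.0, S 1.5, G2 3.0).

*Capture.* Viewpoints are vcp promoters (≥2 per chromosome required; the
window and partner distances shrink together on small genomes so the
precondition can hold). Around each viewpoint, counts cover ±500 fragments
with expectation C·d^(−α), α = 1. Partner triplets (summit + two
shoulders) sit at stratified distances of 150–450 fragments — strata keep
any two partners (and therefore every partner and every mirrored control
site) more than 45 fragments apart, so control windows see pure background.
Partner expectation is background × enrichment (3 at the summit, √3 at
shoulders), ×2 (the G2 boost) in G2, and reset to background in the
knockout, so the expected G2/G1 summit ratio equals the boost exactly.
Scores are 5·ln(e)/ln(√3) of the expected enrichment e — exactly 5 at true
shoulder fragments, 0 at background — and accessible (ATAC) intervals
cover the triplets plus background decoys. The minimum partner distance of
150 fragments keeps the aggregated control profile's max/median below 1.5
at α = 1 over a ±40 window.

*RA response.* Nine conditions (3 phases × 0h/6h-UNT/6h-IAA) × 3
replicates, NB dispersion 0.1, base mean 200. With effect f = 4: cluster I
×f at 6 h under both treatments; cluster II ×√f under UNT and ×√f·f under
IAA (a f-fold IAA amplification); II-A additionally ×f in G1 and ×√f in S
under UNT only (the G1 preference is polycomb-dependent, so IAA erases
it); cluster III ×1/f. Cluster II genes are drawn from polycomb targets,
I/III from unbound genes. DE tables come from the simulated replicates:
log₂ ratio of rep-mean (count+1), Welch t on log₂(count+1), BH within
contrast — a deliberately simple stand-in for an external DE fit, which is
out of scope.

What the generator does **not** emulate: read-level sequences and
mappability, replicate batch effects in ChIP/capture, copy-number changes
through S phase, CHiCAGO's statistical model (scores are constructed to
respect the cutoff semantics, not its distribution), or biological
variation in per-gene effect sizes (effects are constant within a class).
Passing recovery tests therefore demonstrates estimator correctness and
calibration under the assumed noise models, not robustness to artefacts
real data may carry.

## Problem sizes

Recovery analyses run at 600 genes (300 bound) and 1e6 reads for ChIP, 500
target genes for nascent RNA, 100 interactions at 1e6 capture reads, and
200 genes per cluster for the RA analysis; the null ANOVA calibration uses
200 single-chromosome simulations of 60 genes, and the knockout-collapse
rate 100 replicate capture simulations. These sizes make the Monte-Carlo
error of each measured quantity small against its tolerance while keeping a
full run of `scripts/acceptance.py` under a minute.

## Known limitations

- The promoter-assignment rule behind published target counts is not
  standardized; absolute target-set sizes are therefore not comparable
  across pipelines, only the class structure is.
- TMM under strong, widespread differential expression (here ~50–67% of
  genes) leaves residual composition bias that attenuates apparent fold
  changes; the clustering is robust to this but absolute log-ratios are
  conservative.
- The Mann–Whitney exact path enumerates up to C(16,8) assignments; for
  larger groups the normal approximation is used, which is slightly
  conservative at the 0.05 level for n ≈ 20 discrete sums.
- `run_pipeline` re-derives read counts for RPM scaling from the library
  manifest written alongside the tracks; externally produced bedGraphs
  without a manifest fall back to coverage totals, which preserves
  within-run comparability but not absolute RPM units.
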