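# Methods

## CCF estimation

The CCF engine converts per-sample read counts into cancer cell fractions
using the standard purity/copy-number adjustment. For each SNV × sample
cell, the covering allele-specific copy-number segment is looked up
(segments 0-based half-open, SNVs 1-based; the lookup is the only place the
conventions meet), the multiplicity m is assigned by maximising the
binomial likelihood Binom(alt | depth, expected-VAF(CCF=1, m)) over
m = 1..major_cn — an SNV cannot occupy more copies than the major allele —
and CCF = mutation copy number / m. Normal copy number is fixed at 2
(autosomes; sex chromosomes are out of scope by default).

Numerical policies, chosen here because the procedure itself does not pin
them down:

* **CCF cap.** Raw estimates in (1, 1.5] are clipped to 1 and flagged
  `capped` — binomial noise around a clonal mutation routinely produces
  estimates slightly above 1, and clipping keeps the truncal peak at 1.
  Estimates above 1.5 are flagged `implausible` and excluded from
  clustering (at 34× and purity 0.7 this removes roughly 2–5% of clonal
  SNVs in the upper binomial tail; they remain in the CCF matrix and the
  filter report). The uncapped value is kept in `ccf_raw`.
* **Low depth.** Cells with depth < 10 are flagged but still contribute to
  cluster likelihoods (a shallow cell carries little weight automatically
  under the read-count likelihood); only cells with no reads or no covering
  segment are treated as missing.
* **Purity from a VAF peak** (targeted data without CN calls): Gaussian KDE
  with Silverman's bandwidth on a 512-point grid over [0, 1]; strict local
  maxima with density ≥ 5% of the global maximum are candidate peaks, the
  one at the highest VAF is the clonal peak, and purity = min(1, 2·peak).
  The 5% floor discards negligible tail wiggles of the KDE.

## Pseudo-heterogeneity filtering

Copy-number differences between samples can mimic subclonal structure. Two
filters run before clustering. (1) CN concordance: an SNV is kept only if
its (major, minor) state is identical in every sample; SNVs without a
covering segment in some sample are removed as ambiguous. (2) Allele-loss:
an SNV counted absent in a sample (CCF < 0.05 **and** ≤ 1 supporting read —
the joint condition resists depth noise) is removed when that sample shows
LOH at the locus while every SNV-bearing sample retains both alleles, or a
lower total copy number than every SNV-bearing sample. The reading of
"copy number could explain the loss" is deliberately conservative: a false
subclonal cluster is more damaging to tree reconstruction than discarding a
recoverable SNV. On fully diploid data (including all simulated designs)
the filters remove nothing, and they are idempotent.

## Dirichlet-process clustering

The mixture is a truncated stick-breaking DP with K = 30 components. The
likelihood works on raw read counts — Binom(alt | depth, c·f) per cell,
with f the clonal VAF scale — rather than Gaussian noise on CCF points, so
deep cells constrain locations more than shallow ones; CCF points are used
only to initialise (k-means with 10 centres) and to report. Priors and
updates:

* component locations: independent Uniform(0, 1.2) per sample, allowing
  mild super-clonal mass before the summary cap at 1; resampled by grid
  Gibbs on a 0..1.2 grid with step 0.005 from the discretised conditional
  posterior (no proposal tuning, deterministic given the seed);
* stick weights: Beta conditionals; concentration α ~ Gamma(1, 1),
  resampled every sweep from its conjugate conditional;
* assignments: categorical conditionals sampled via the Gumbel-max trick.

Defaults are 2,000 sweeps, 1,000 burn-in, thinning 10 (100 retained
samples); on ~5,000–8,000 SNVs × 4 samples a fit takes tens of seconds.
Per-sample binomial terms are grouped by their clonal-VAF scale factor, so
the location updates reduce to a handful of sufficient statistics per
component and the sweep cost is dominated by the n × K assignment step.

**Cluster calling.** Posterior summaries of DP mixtures suffer label
switching, so averaging locations per component index is unsafe. Clusters
are instead fixed at the retained iteration with the highest joint log
density; each occupied component's location is then refined to the peak of
its conditional posterior density given that assignment (grid maximum
likelihood), components agreeing within the merge tolerance (0.05) in every
sample are merged, and every SNV is reassigned to its maximum-posterior
cluster. This keeps the "peaks of the posterior mutation density"
interpretation while being stable across seeds (locations reproduce within
0.05 on the simulated designs).

**Labels.** Per sample, a cluster is clonal when its location is within 0.1
of CCF 1, absent below 0.05, otherwise subclonal; the cluster clonal in
every sample is truncal. The tolerances separate the generating levels
0.3 / 0.7 / 1.0 used throughout the validation designs. Clusters below 1%
of clustered SNVs are dropped in the pipeline's final cluster set (their
SNVs become unassigned); recovery analyses inspect the called set before
this size filter, since a 50-SNV branch on a 5,000-SNV trunk sits just
under 1% at desk scale.

## Clone-tree reconstruction

Trees over clusters, rooted at the truncal cluster, are enumerated
depth-first over per-cluster parent candidates (clusters that dominate
them), checking the sum rule incrementally at each parent and the crossing
rule against ancestors and descendants. All three rules hold exactly only
under the infinite sites assumption with noiseless CCFs; estimated
locations get a uniform tolerance eps = 0.1 in every comparison. All valid
trees are returned, ranked by total consumed slack (the summed amount by
which dominance and sum constraints rely on eps) — most parsimonious first;
ties are broken deterministically by topology. Enumeration is bounded at 12
clusters and 5·10⁶ visited partial states; beyond that it fails loudly
rather than answer heuristically.

If no valid tree exists, the cluster implicated in the most unresolvable
pairwise conflicts (no dominating parent; crossing pairs no ancestor can
host under the sum rule) is removed — ties broken towards fewer SNVs — and
enumeration retried. In practice this prunes the occasional singleton
artefact cluster the sampler leaves behind.

Sample subtrees are induced on nodes with CCF > 0.05 in the sample, with
excluded intermediate nodes bridged over and the root always retained.
Drivers are annotated on the node of their assigned cluster, in input
order; unassignable drivers are reported, not fatal.

## The simulator and what it does (not) emulate

The simulator draws, per SNV × sample, depth ~ Poisson(λ = 34) and alt
reads ~ Binomial(depth, expected VAF of the cluster's true CCF given purity
and local copy number). The six standard validation designs are: (1) a
truncal-only genome of 100,000 SNVs; (2–6) the same trunk plus six
non-truncal clusters in three bifurcations — two mutually exclusive clonal
clusters (CCF 1 in samples 1–2 and 3–4 respectively) each carrying two
second-step subclonal branches at mean CCFs 0.7 and 0.3 — at per-branch
burdens 50, 100, 150, 200 and 500 (totals 100,300–103,000). Four samples;
purities drawn uniformly in [0.70, 0.95] from the spec seed, overridable.
Which sample carries which lineage, and the one-subclone-per-sample layout
of the second-step branches, are choices made here; they match the
requirement that a 0.7-CCF cluster unique to one sample be distinguishable
from a clonal cluster shared by two samples, and make the generating
topology uniquely identifiable under the three rules.

All simulated loci are diploid with multiplicity 1 — the validation designs
probe cluster/tree recovery, not CN handling, which is exercised by unit
tests instead. The simulator does not model sequencing error, mapping bias,
FFPE artefacts, indels, rearrangements or trinucleotide context; passing
recovery tests therefore demonstrates statistical identifiability of the
clonal structure at the stated depth/purity, not robustness to artefact
processes in real data. Depth-0 cells are retained (alt = 0) and must be
tolerated downstream.

Desk-scale runs shrink the trunk only (recovery analyses use 5,000 trunk
SNVs with branch burdens unchanged), preserving the branch structure while
keeping a full clustering run within tens of seconds; full-scale designs
(100,000+ SNVs) are generated in milliseconds but are only counted, not
clustered, in the test suite.

## Validation calling

A discovery call is validated somatic when the orthogonal capture
experiment shows ≥ 2 alternate reads; cells under 30× capture coverage are
excluded from both numerator and denominator. Detection in an archival
primary uses the ≥ 2-read threshold alone. Rates are reported overall and
per group (e.g. per cluster). Thresholds are inclusive at the boundary
(exactly 2 reads validates; exactly 30× is assessable).

## Known limitations

* The DP sampler is a single chain; multimodality is addressed by the
  k-means initialisation and checked by cross-seed agreement, not by
  parallel tempering.
* Cluster-calling fixes one posterior iteration's partition; posterior
  uncertainty in the number of clusters is visible in the trace but not
  propagated into the tree.
* Tree enumeration is exact but exponential; more than 12 clusters require
  prior pruning.
* Purity-from-VAF-peak assumes the clonal peak is the highest-VAF mode;
  heavy subclonal burden above the clonal peak (or CN-shifted loci) would
  mislead it, which is why the diploid-locus restriction matters.
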