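# Methods

This note documents the models, parameter choices and numerical conventions
behind `otomics`, and what the synthetic-data experiments do and do not
demonstrate.

## Consensus clustering

Samples are clustered from an item × item dissimilarity computed once on
the full data: Pearson dissimilarity d = 1 − r over feature vectors
(pairwise-complete when values are missing; a pair sharing fewer than 3
features gets an undefined dissimilarity, imputed as the row maximum so the
linkage stays total) or NaN-aware Euclidean distance. Each of `n_iter`
iterations (default 1000) draws a subsample of the samples (fraction 0.8,
without replacement — the subsample fraction is a conventional default, and
only samples are resampled, so restricting the precomputed dissimilarity to
the subsample is exact). Ward linkage is run once per iteration and cut at
every K in the candidate range (default 2–8); the consensus matrix per K is
the ratio of co-clustering to co-sampling counts. Final labels per K come
from Ward clustering of 1 − M_K cut into K groups.

Two Ward variants are provided because scipy's `ward` on a condensed
distance matrix behaves as R's `ward.D2` (equivalently: the classic
Lance–Williams recurrence applied to squared input dissimilarities).
Pearson mode uses this classic form directly (`scipy ward` on d); Euclidean
mode reproduces R's `ward.D` on d by feeding `scipy ward` the square root
of d — the same tree up to a monotone transform of merge heights. The
Euclidean/`ward.D` combination is the convention for methylation beta
values; Pearson/classic Ward for expression.

### Model selection

A(K) is the exact area under the empirical CDF of the off-diagonal
consensus entries (piecewise integration of the step function on [0, 1],
no histogram binning). The selected K is the largest one with relative
gain Δ(K) = (A(K) − A(K−1))/A(K−1) ≥ 0.10, with Δ(k_min) = A(k_min). The
0.10 threshold is an explicit, configurable stand-in for the visual
"shape of the CDF" judgement; the full area and Δ curves are always
returned so a user can override the automatic choice.

Known limitations: (i) on pure noise the area criterion does **not**
collapse — Δ stays above threshold for several K, so a homogeneous cohort
will be split rather than flagged; the weak-structure flag fires only when
the Δ curve is genuinely flat beyond k_min. (ii) With markedly unbalanced
groups the Δ rule merges the smallest classes (e.g. the default
study-shaped cohort selects K = 4, merging the two smallest subtypes);
recovering fine structure then requires re-clustering the subset of
interest, which is how the original analyses proceeded as well.

### Contamination screening

A preliminary clustering including normal-brain controls identifies the
normal-like class: any class containing ≥ 50% of all controls. Tumours in
that class are treated as contaminated with non-neoplastic tissue and
removed before subtyping. On generated cohorts with mixing weight w = 0.8
the screen recovers essentially all planted contaminated tumours.

## Cluster-of-clusters integration

Per-omic partitions are one-hot encoded per class, with NA over a whole
block when the sample was not classified at that omic. The encoded rows are
consensus-clustered with Pearson dissimilarity (pairwise-complete columns,
so an absent omic simply contributes nothing for that sample). Integration
accuracy is bounded by the information in the partitions: a sample whose
informative omics split 1–1 between two classes is irreducibly ambiguous,
and with 10% per-omic label noise and 15% per-omic missingness about 4% of
samples fall in that regime, capping the expected adjusted Rand index near
0.91 for any integration method (a majority-vote decoder measures the same
bound). Tests and the recovery experiment interpret results against that
ceiling.

## miRNA preprocessing

miRNAs are kept when they exceed 10 reads in at least two samples. The
normalization follows the unusual but deliberate order: log2(count + 1)
first, then division by each sample's total raw read count (rescaled by
10⁶ so values keep a convenient magnitude), then per-miRNA mean centring.
A `cpm_first` switch provides the conventional counts-per-million-then-log2
order; totals are always raw (pre-filter) library sizes.

## Copy-number and methylation events

Coordinates are 1-based inclusive on hg19; arm boundaries ship as a
packaged table (39 autosomal arms, acrocentric p arms excluded, plus
Xp/Xq). Gene-level events from segment data require the region to be fully
covered with every overlapping segment carrying the target sign — partial
or mixed-sign coverage is a negative call, no overlap at all is NA. Arm
calls use an 80%-of-covered-length rule with a 50% minimum coverage floor;
both thresholds are configurable since any aggregation rule at arm level is
a convention.

Expression-based 1p/19q co-deletion: per sample, the mean centred
expression of 1p probes and of 19q probes is averaged into a single score
u, and the exact 1-D two-class split minimizing total within-class variance
is found by scanning the sorted scores (deterministic, seed-free; each side
must keep ≥ 2 samples). Centring is double — per-gene cohort means, then
per-sample residual means — so the call is invariant both to gene-level
baselines and to constant per-sample technical offsets.

Single-CpG calls: MYC exon 3 hypomethylation is beta < 0.5 at cg00163372
(strict inequality); mir34b/c promoter hypermethylation is beta above the
dataset mean + 2·SD (n − 1 denominator) at cg22879515, with the threshold
recomputed per dataset when cohorts are pooled. The three further island
probes (cg21881253, cg13767940, cg23211240) are exposed read-only. CIMP
status restricts consensus clustering (Euclidean/Ward) to island CpGs, cuts
at K = 2 and labels the class with the higher mean beta positive — polarity
is defined by methylation level, never by cluster id.

## Moderated t and enrichment

The empirical-Bayes variance prior (d0, s0²) is fitted by matching moments
of log s² to the log of a scaled F distribution: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess variance of e over
ψ′(d/2) determines d0 through the trigamma inverse (Newton iteration), and
its mean determines s0². d0 = 0 reduces exactly to the ordinary
equal-variance t; d0 = ∞ pins all variances at s0². Features constant in
both groups carry no evidence and get NA p-values. No multiple-testing
adjustment is applied by default (Benjamini–Hochberg behind a flag), and
signatures take the top-n features by fold change among those with
unadjusted p < 0.05 and positive log fold change (n = 100 by default).
Gene-set enrichment is the upper-tail hypergeometric probability of the
observed overlap. The MYC activity score is the per-sample mean of
(gene-centred by default) expression over a user-supplied target list.

## Exclusivity and survival

Mutual exclusivity of two event types is a one-sided binomial test: on
samples with both calls defined, the co-occurrence count k is referred to
Binomial(n, pA·pB) with marginal rates as observed, p = P[X ≤ k]. The
independence null with plugged-in marginals is the natural reading of a
co-occurrence test when only marginal frequencies are reported; observed
and expected counts are returned alongside p.

Kaplan–Meier estimation and the multi-group log-rank test are delegated to
lifelines (deaths processed before censorings at ties); a two-group
cohort-stratified variant sums per-stratum O − E and hypergeometric
variances. Pooled comparisons report the unstratified test (default) and
the stratified one alongside when two groups span several cohorts. The
radiotherapy analysis excludes patients deceased within 3 months of
diagnosis (they could not have effectively received radiotherapy), censors
everyone at the 60-month horizon, and runs a log-rank of RT vs no-RT within
each subtype; strata with fewer than 2 patients per arm return NA with a
note. The 3-month landmark applies only there, not in plain pooling.

## Cross-cohort class matching

Centroids are per-class mean expression profiles over a dataset's 10% most
variant genes. For a pair of datasets the 10% selection is recomputed on
the genes measured in both (within each dataset, then intersected; if the
selections barely overlap the union is used with a warning), and centroids
are correlated on that pair-specific gene set — so the full centroid ×
centroid distance matrix deliberately mixes gene universes across pairs.
Average-linkage hierarchical clustering of 1 − r cut into `n_meta` groups
(default 3, explicit otherwise) yields the meta-classes; a warning reports
any meta-class missing a dataset.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes. Defaults
describe a study-shaped cohort: five subtypes sized (47, 25, 36, 17, 16),
three of them 1p/19q co-deleted, 9 normal controls and 29 tumours
contaminated by normal tissue (convex mixture of mean profiles, w = 0.8).
Expression is baseline N(7, 1) per gene plus additive subtype signatures
(40 genes per subtype, +2 log2 units), a −0.3 shift on 50 probes per
co-deleted arm, a +1 shift on 30 MYC target genes for samples carrying at
least one MYC event, and N(0, 1) noise. miRNA counts are negative binomial
(dispersion 0.3) around subtype-shifted means with log-normal sequencing
depths; methylation is logit-normal with a CIMP island offset (+1.5 logit)
in the *IDH*-mutant-like subtypes, per-subtype CpG signatures, and the two
single-CpG event probes driven solely by their planted events. Copy-number
segments cover every arm for every sample, with 1p/19q loss in co-deleted
samples, aggressive-subtype arm losses tuned so ≈ 66% carry at least one of
the 4/9p/14q/18q losses, focal MYC gain carved out of 8q, and MAX loss
expressed as 14q arm loss. The aggressive subtype's MYC-event probabilities
are (0.09, 0.35, 0.20, 0.28); other subtypes use a 0.02 background rate; an
`exclusive` mode draws at most one event per sample. Survival is
exponential per subtype (0.012/month aggressive, 0.006 other co-deleted,
0.02 *IDH*-wildtype-like, 0.008 *IDH*-mutant non-co-deleted) with
independent exponential censoring (0.004/month, capped at 180 months) and a
radiotherapy hazard ratio of 0.4 confined to the aggressive subtype —
exponential rather than Weibull so tests have closed-form expectations.

An optional `baseline_seed` lets several cohorts share per-feature
baselines while differing in membership, noise and events: gene-level
baseline expression is conserved across real datasets, and cross-cohort
centroid matching depends on exactly that conservation. Without it,
independently drawn baselines make class centroids nearly orthogonal across
cohorts and matching degenerates — a property of the simulation, not of the
method.

What the generator does not emulate: probe-level array artefacts, batch
effects, copy-number-driven expression dosage, non-proportional hazards,
or correlated missingness between omics. Passing recovery tests therefore
demonstrates correctness of the algorithms under the assumed generative
structure, not robustness to the technical noise of real cohorts.

## Problem sizes in tests and the acceptance script

Recovery experiments use cohort-scale sizes chosen a priori: 120 samples /
5 subtypes for consensus recovery, 150 samples for integration recovery,
150 samples at noise 0.2 for the co-deletion caller, 4 × 90 samples for
cross-cohort matching, 500 replicates at n = 50/group for log-rank
calibration, and 240/100/100 for the radiotherapy localisation experiment
(sized by a power calculation at hazard ratio 0.4 under the 3-month
landmark and 5-year horizon: ≈ 70 events in the aggressive stratum for 97%
power). The acceptance script runs the full pipeline on the default
study-shaped cohort at 1000 consensus iterations and completes in well
under a minute on one CPU.
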