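# otomics

Multi-omics consensus subtyping of oligodendroglial tumours (OT) — gliomas
whose molecular backbone is the 1p/19q co-deletion and the *IDH* mutation.
The package re-implements, as a tested and reusable pipeline, an integrative
analysis that classifies tumours from mRNA expression, miRNA sequencing and
DNA methylation independently, fuses the three classifications by a
"cluster of clusters" step, and then characterizes the resulting subtypes:
copy-number and methylation events converging on MYC activation in the
aggressive OPC-like group, and survival differences including a
radiotherapy-benefit analysis. Because the cohorts behind such studies are
controlled-access, the package ships a synthetic multi-omics cohort
generator with ground truth, so every stage is exercised and its recovery
quantified without external data.

It is aimed at computational biologists who want the individual building
blocks (consensus clustering with CDF-area model selection, moderated-t
differential expression, GNL event calling, centroid-based cross-cohort
class matching, Kaplan–Meier/log-rank comparisons) as well as the
end-to-end chain.

## The methods in brief

**Consensus clustering.** For K = 2…8, samples are repeatedly subsampled
(80%, 1000 iterations), clustered hierarchically (Pearson dissimilarity
1 − r or Euclidean distance; Ward linkage) and the consensus matrix
M_K(i,j) — the fraction of co-sampled iterations in which i and j
co-cluster — is accumulated. With A(K) the area under the empirical CDF of
the off-diagonal entries of M_K, the selected K is the largest one whose
relative gain Δ(K) = (A(K) − A(K−1))/A(K−1) is at least 0.10; the full Δ
curve is reported so the automatic choice can be overridden.

**Cluster of clusters.** Each per-omic partition becomes one binary
indicator column per class (NA when a sample is not classified at that
molecular level); samples are consensus-clustered on these indicator rows
to give the integrated multi-omics partition.

**Moderated t.** Per-gene variances s² (d degrees of freedom) are shrunk
towards an empirical-Bayes prior s² ~ s0²·F(d, d0) fitted by matching the
moments of log s²; the test statistic is t̃ = (x̄₁ − x̄₀)/(s̃·√(1/n₁+1/n₀))
with s̃² = (d0·s0² + d·s²)/(d0 + d) on d0 + d degrees of freedom.

**MYC deregulation.** Four events are called per sample: MYC locus gain and
MAX locus loss from gain/normal/loss (GNL) copy-number data ("all positions
within the gene region carry the sign"), MYC exon 3 hypomethylation (beta
at cg00163372 < 0.5) and mir34b/c promoter hypermethylation (beta at
cg22879515 above the cohort mean + 2·SD). MYC activity is the per-sample
mean expression of a MYC target list; mutual exclusivity between events is
tested by a one-sided binomial test of the co-occurrence count against the
product of the marginal rates.

**Survival.** Kaplan–Meier curves and log-rank tests, cohort pooling, and a
radiotherapy-stratified comparison that excludes patients deceased within 3
months of diagnosis and censors follow-up at five years.

## Worked example

```python
from otomics import CohortConfig, generate_cohort
from otomics.pipeline import run_standard_pipeline
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(CohortConfig(seed=1))      # 179 samples, 3 omics
result = run_standard_pipeline(cohort, n_iter=1000, seed=2)

print("contaminated tumours flagged:", len(result.flagged_contaminated))
print("per-omic K:", {k: r.selected_k for k, r in result.per_omic.items()})
labels = result.integrated.selected_labels()
truth = cohort.truth.loc[labels.index, "subtype"]
print("integrated ARI vs truth:", round(adjusted_rand_score(truth, labels), 3))
print("MYC events (aggressive subtype):")
agg = cohort.truth["subtype"] == "C1"
print(result.event_table.loc[agg.reindex(result.event_table.index, fill_value=False)]
      [["myc_gain", "max_loss", "myc_hypometh", "mir34_hypermeth"]].mean())
```

Output (seed 1):

```
contaminated tumours flagged: 29
per-omic K: {'mrna': 4, 'mirna': 4, 'methylation': 4}
integrated ARI vs truth: 0.925
MYC events (aggressive subtype):
myc_gain           0.085106
max_loss           0.297872
myc_hypometh       0.108108
mir34_hypermeth    0.378378
```

All 29 tumours planted as contaminated with normal brain tissue cluster
with the normal controls and are removed; the integrated partition matches
the planted subtypes (ARI 0.93 — the two smallest subtypes merge at the
automatically selected K, exactly the regime where the original analysis
re-clustered the co-deleted tumours separately); the called MYC event
frequencies in the aggressive subtype track the planted probabilities
(0.09, 0.35, 0.20, 0.28) within binomial noise at n = 47.

The same stages are available from the shell:

```bash
otomics synth --seed 1 --out cohort/
otomics cluster --matrix cohort/mrna.tsv --omic mrna --seed 2 --out mrna_out/
otomics integrate --labels mrna_out/labels.tsv --labels meth_out/labels.tsv \
    --seed 2 --out integrated/
otomics events --gnl cohort/gnl_segments.tsv --methylation cohort/methylation.tsv \
    --out events.tsv
```

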