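"""Convenience driver chaining the standard analysis end-to-end.

Mirrors the study workflow: preliminary mRNA consensus clustering with the
normal controls to flag and remove contaminated tumours, per-omic consensus
clustering of the cleaned cohort (mRNA and miRNA with Pearson dissimilarity,
methylation with Euclidean), cluster-of-clusters integration, MYC event
calling and activity scoring, and the survival comparison of the aggressive
group against the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consensus import ConsensusResult, consensus_cluster, flag_contamination, select_variant_features
from .de import myc_activity_score
from .events import (
    MAX_REGION_HG19,
    MYC_REGION_HG19,
    call_cpg_hypermethylation,
    call_cpg_hypomethylation,
    call_gene_event,
)
from .integration import cluster_of_clusters, crosstab_association, encode_partitions, mirna_preprocess
from .myc import aggregate_events
from .simulate import SyntheticCohort
from .survival import pooled_survival
from .types import GeneSet, OmicsMatrix


@dataclass
class PipelineResult:
    flagged_contaminated: list[str]
    per_omic: dict[str, ConsensusResult]
    partitions: dict[str, pd.Series]
    integrated: ConsensusResult
    event_table: pd.DataFrame
    associations: dict[str, tuple[float, float]]
    survival: dict | None


def run_standard_pipeline(
    cohort: SyntheticCohort,
    n_iter: int = 1000,
    seed: int = 0,
    k_range=range(2, 9),
    mirna_fraction: float = 0.25,
) -> PipelineResult:
    """Run the full subtyping analysis on a (synthetic) cohort."""
    # 1. preliminary clustering with controls; remove contaminated tumours
    feats = select_variant_features(cohort.mrna, 0.05)
    pre = consensus_cluster(
        OmicsMatrix(cohort.mrna.values.loc[feats], "mrna"),
        k_range=k_range, n_iter=n_iter, seed=seed,
    )
    flagged = flag_contamination(pre.selected_labels(), cohort.annot)
    controls = set(cohort.annot.index[cohort.annot["is_normal_control"].astype(bool)])
    keep = [s for s in cohort.mrna.sample_ids if s not in set(flagged) | controls]

    # 2. per-omic consensus clustering of the cleaned tumour cohort
    per_omic: dict[str, ConsensusResult] = {}
    partitions: dict[str, pd.Series] = {}

    mrna = cohort.mrna.subset_samples(keep)
    feats = select_variant_features(mrna, 0.05)
    per_omic["mrna"] = consensus_cluster(
        OmicsMatrix(mrna.values.loc[feats], "mrna"),
        k_range=k_range, n_iter=n_iter, seed=seed,
    )

    mir_samples = [s for s in cohort.mirna_counts.columns if s in keep]
    mirna = mirna_preprocess(cohort.mirna_counts[mir_samples])
    feats = select_variant_features(mirna, mirna_fraction)
    per_omic["mirna"] = consensus_cluster(
        OmicsMatrix(mirna.values.loc[feats], "mirna"),
        k_range=k_range, n_iter=n_iter, seed=seed,
    )

    meth = cohort.methylation.subset_samples(
        [s for s in cohort.methylation.sample_ids if s in keep]
    )
    feats = select_variant_features(meth, 0.05)
    per_omic["methylation"] = consensus_cluster(
        OmicsMatrix(meth.values.loc[feats], "methylation"),
        k_range=k_range, n_iter=n_iter, distance="euclidean", seed=seed,
    )
    for name, res in per_omic.items():
        partitions[name] = res.selected_labels().rename(name)

    # 3. cluster-of-clusters integration
    indicator = encode_partitions(list(partitions.values()))
    integrated = cluster_of_clusters(indicator, k_range=k_range, n_iter=n_iter, seed=seed)
    associations = {}
    for name, part in partitions.items():
        _, stat, p = crosstab_association(integrated.selected_labels(), part)
        associations[name] = (stat, p)

    # 4. MYC events and activity
    myc_gain = call_gene_event(cohort.gnl, MYC_REGION_HG19, "gain")
    max_loss = call_gene_event(cohort.gnl, MAX_REGION_HG19, "loss")
    idx = pd.Index(keep)
    hypo = call_cpg_hypomethylation(cohort.methylation).reindex(idx)
    hyper, _ = call_cpg_hypermethylation(cohort.methylation)
    targets = GeneSet("myc_targets", tuple(cohort.myc_target_genes), source="generator")
    score, _ = myc_activity_score(mrna, targets)
    etable = aggregate_events(
        myc_gain.reindex(idx), max_loss.reindex(idx), hypo, hyper.reindex(idx),
        myc_score=score.reindex(idx),
    )

    # 5. survival: aggressive integrated class vs the rest
    surv = None
    annot = cohort.annot.loc[keep]
    labels = integrated.selected_labels().reindex(idx)
    if labels.notna().any() and annot["os_event"].notna().any():
        agg_class = (
            etable["myc_score"].groupby(labels).mean().idxmax()
        )  # class with highest MYC activity, the aggressive candidate
        rec = pd.DataFrame(
            {
                "os_time": annot["os_time"],
                "os_event": annot["os_event"],
                "group": (labels == agg_class).map({True: "aggressive", False: "other"}),
            }
        ).dropna()
        if rec["group"].nunique() == 2 and rec["os_event"].sum() > 0:
            surv = pooled_survival([("cohort", rec)])
            surv.pop("records", None)
            surv["aggressive_class"] = agg_class

    return PipelineResult(
        flagged_contaminated=flagged,
        per_omic=per_omic,
        partitions=partitions,
        integrated=integrated,
        event_table=etable,
        associations=associations,
        survival=surv,
    )
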