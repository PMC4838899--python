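"""Copy-number and methylation event calling.

Gene-level gain/loss calls from GNL segments ("all positions within the
gene region carry the target sign"), arm-level status aggregation,
expression-based 1p/19q co-deletion assignment, single-CpG hypo/hyper-
methylation calls, and CIMP status from island-restricted consensus
clustering.

Coordinates are 1-based inclusive (hg19); the packaged arm table supplies
arm boundaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .consensus import consensus_cluster, select_variant_features
from .types import GNLTable, OmicsMatrix, ValidationError, load_arm_table

__all__ = [
    "MYC_REGION_HG19",
    "MAX_REGION_HG19",
    "MYC_EXON3_CPG",
    "MIR34BC_CPG",
    "MIR34BC_CPGS_ALL",
    "call_gene_event",
    "call_arm_status",
    "codel_from_expression",
    "call_cpg_hypomethylation",
    "call_cpg_hypermethylation",
    "cimp_status",
]

#: MYC locus on 8q24 (hg19, 1-based inclusive).
MYC_REGION_HG19 = ("8", 128_748_315, 128_753_680)
#: MAX locus on 14q23 (hg19, 1-based inclusive).
MAX_REGION_HG19 = ("14", 65_472_892, 65_569_413)

#: CpG probe on MYC exon 3 used for the hypomethylation call.
MYC_EXON3_CPG = "cg00163372"
#: CpG probe in the mir34b/c promoter island used for the hypermethylation call.
MIR34BC_CPG = "cg22879515"
#: All four mir34b/c island probes hypermethylated in the aggressive subtype;
#: only the first drives calls, the rest are exposed for inspection.
MIR34BC_CPGS_ALL = ("cg22879515", "cg21881253", "cg13767940", "cg23211240")


def _overlap(seg_start, seg_end, start, end):
    return np.maximum(
        0, np.minimum(seg_end, end) - np.maximum(seg_start, start) + 1
    )


def call_gene_event(gnl: GNLTable, gene_region, direction: str) -> pd.Series:
    """Per-sample boolean: does the gene region carry a uniform gain/loss?

    Segment mode: True iff the region is fully covered by segments and every
    overlapping segment has the target sign (gain: +1/+2, loss: −1/−2);
    False if any overlapping segment has another sign or coverage is
    incomplete; NA if no segment overlaps the region at all.

    Gene mode: ``gene_region`` is the gene id and the call is a simple sign
    match of that gene's GNL value.
    """
    if direction not in ("gain", "loss"):
        raise ValidationError("direction must be 'gain' or 'loss'")
    sign = 1 if direction == "gain" else -1
    if gnl.mode == "gene":
        gene = gene_region
        if gene not in gnl.genes.index:
            raise ValidationError(f"gene {gene!r} absent from gene-level GNL table")
        row = gnl.genes.loc[gene]
        return row.map(lambda v: np.nan if pd.isna(v) else bool(np.sign(v) == sign))

    chrom, start, end = gene_region
    region_len = end - start + 1
    seg = gnl.segments
    out = {}
    for sample, grp in seg.groupby("sample", sort=False):
        on = grp[grp["chrom"].astype(str) == str(chrom)]
        ov = _overlap(on["start"].to_numpy(), on["end"].to_numpy(), start, end)
        hit = ov > 0
        if not hit.any():
            out[sample] = np.nan
            continue
        covered = int(ov[hit].sum())
        signs_ok = np.sign(on["gnl"].to_numpy()[hit]) == sign
        out[sample] = bool(signs_ok.all() and covered >= region_len)
    return pd.Series(out, name=f"{direction}")


def call_arm_status(
    gnl: GNLTable,
    arm: str,
    sign_fraction: float = 0.8,
    min_coverage: float = 0.5,
) -> pd.Series:
    """Per-sample arm-level call in {−1, 0, +1} (NA when coverage < 50%).

    The arm is called gained (+1) or lost (−1) when at least
    ``sign_fraction`` of its covered length carries that sign, else neutral.
    """
    if gnl.mode != "segment":
        raise ValidationError("arm calls need segment-mode GNL data")
    arms = load_arm_table().set_index("arm")
    if arm not in arms.index:
        raise ValidationError(f"unknown arm {arm!r}")
    chrom, start, end = arms.loc[arm, ["chrom", "start", "end"]]
    arm_len = end - start + 1
    out = {}
    for sample, grp in gnl.segments.groupby("sample", sort=False):
        on = grp[grp["chrom"].astype(str) == str(chrom)]
        ov = _overlap(on["start"].to_numpy(), on["end"].to_numpy(), start, end)
        hit = ov > 0
        covered = ov[hit].sum()
        if covered < min_coverage * arm_len:
            out[sample] = np.nan
            continue
        g = on["gnl"].to_numpy()[hit]
        pos = ov[hit][g > 0].sum()
        neg = ov[hit][g < 0].sum()
        if pos >= sign_fraction * covered:
            out[sample] = 1
        elif neg >= sign_fraction * covered:
            out[sample] = -1
        else:
            out[sample] = 0
    return pd.Series(out, name=f"arm_{arm}")


def codel_from_expression(mrna: OmicsMatrix, min_features_per_arm: int = 5):
    """Expression-based 1p/19q co-deletion assignment.

    Per sample, compute the mean centred expression of 1p probes (m1p) and
    of 19q probes (m19q); project onto u = (m1p + m19q) / 2 and find the
    two-class split of the sorted u values that minimizes total within-class
    variance (exact 1-D scan, deterministic). The class with the lower mean
    u is labelled co-deleted.

    Centring is double: each gene's cohort mean is removed (so gene-level
    baselines cancel) and then each sample's residual mean over all genes
    (so constant per-sample technical offsets cancel too).

    Returns ``(codel, scores)``: a boolean Series (all-NA on a degenerate
    no-call) and a frame with columns m1p, m19q, u.
    """
    if mrna.feature_annot is None or "arm" not in mrna.feature_annot.columns:
        raise ValidationError("codel_from_expression needs arm annotations")
    arm = mrna.feature_annot["arm"]
    centred = mrna.values.sub(mrna.values.mean(axis=1), axis=0)
    centred = centred.sub(centred.mean(axis=0), axis=1)
    scores = {}
    for a in ("1p", "19q"):
        feats = arm.index[arm == a].intersection(mrna.values.index)
        if len(feats) < min_features_per_arm:
            raise ValidationError(f"need >= {min_features_per_arm} features on {a}")
        scores[f"m{a}"] = centred.loc[feats].mean(axis=0)
    scores = pd.DataFrame(scores)
    scores["u"] = (scores["m1p"] + scores["m19q"]) / 2.0

    u = scores["u"].to_numpy()
    order = np.argsort(u, kind="stable")
    su = u[order]
    n = len(su)
    nocall = pd.Series(np.nan, index=scores.index, name="codel")
    if n < 4 or np.allclose(su, su[0]):
        warnings.warn("degenerate expression scores; no co-deletion call", stacklevel=2)
        return nocall, scores
    best_i, best_cost = None, np.inf
    csum = np.cumsum(su)
    csq = np.cumsum(su**2)
    for i in range(2, n - 1):  # >= 2 samples on each side
        left_ss = csq[i - 1] - csum[i - 1] ** 2 / i
        right_n = n - i
        rsum = csum[-1] - csum[i - 1]
        right_ss = (csq[-1] - csq[i - 1]) - rsum**2 / right_n
        cost = left_ss + right_ss
        if cost < best_cost - 1e-15:
            best_cost, best_i = cost, i
    if best_i is None:
        warnings.warn("no valid two-class split; no co-deletion call", stacklevel=2)
        return nocall, scores
    codel_mask = np.zeros(n, dtype=bool)
    codel_mask[order[:best_i]] = True  # lower-u side
    codel = pd.Series(codel_mask, index=scores.index, name="codel")
    return codel, scores


def _cpg_row(methylation: OmicsMatrix, cpg_id: str) -> pd.Series:
    if cpg_id not in methylation.values.index:
        raise ValidationError(f"CpG {cpg_id!r} absent from methylation matrix")
    return methylation.values.loc[cpg_id]


def call_cpg_hypomethylation(
    methylation: OmicsMatrix, cpg_id: str = MYC_EXON3_CPG, threshold: float = 0.5
) -> pd.Series:
    """True iff beta at ``cpg_id`` is strictly below ``threshold`` (NA beta → NA)."""
    beta = _cpg_row(methylation, cpg_id)
    return beta.map(lambda b: np.nan if pd.isna(b) else bool(b < threshold))


def call_cpg_hypermethylation(
    methylation: OmicsMatrix, cpg_id: str = MIR34BC_CPG, min_samples: int = 10
):
    """True iff beta exceeds the cohort mean + 2·SD at ``cpg_id``.

    The threshold is computed over all non-NA samples of the dataset (SD
    with n−1 denominator). Returns ``(calls, threshold)``; an SD of zero
    yields all-False with a warning.
    """
    beta = _cpg_row(methylation, cpg_id)
    obs = beta.dropna()
    if len(obs) < min_samples:
        raise ValidationError(
            f"need >= {min_samples} non-NA samples at {cpg_id}, have {len(obs)}"
        )
    mean, sd = obs.mean(), obs.std(ddof=1)
    threshold = mean + 2.0 * sd
    if sd <= 1e-12 * max(1.0, abs(mean)):
        warnings.warn(f"zero SD at {cpg_id}; no sample called", stacklevel=2)
        calls = beta.map(lambda b: np.nan if pd.isna(b) else False)
        return calls, float(threshold)
    calls = beta.map(lambda b: np.nan if pd.isna(b) else bool(b > threshold))
    return calls, float(threshold)


def cimp_status(
    methylation: OmicsMatrix,
    fraction: float = 0.05,
    n_iter: int = 250,
    seed: int = 0,
    min_separation: float = 0.02,
) -> pd.Series:
    """CpG Island Methylator Phenotype call.

    Consensus-clusters samples on the most variant island CpGs (Euclidean
    distance, Ward linkage) into two classes; the class with the higher mean
    beta over the selected CpGs is CIMP-positive. Polarity is defined by the
    mean beta, never by the class id.
    """
    if methylation.feature_annot is None or "cpg_island" not in methylation.feature_annot.columns:
        raise ValidationError("cimp_status needs cpg_island feature annotation")
    island = methylation.feature_annot.index[
        methylation.feature_annot["cpg_island"].fillna(False).astype(bool)
    ]
    island = island.intersection(methylation.values.index)
    if len(island) == 0:
        raise ValidationError("no island CpGs in matrix")
    sub = OmicsMatrix(methylation.values.loc[island], "methylation")
    feats = select_variant_features(sub, fraction)
    sel = OmicsMatrix(sub.values.loc[feats], "methylation")
    res = consensus_cluster(
        sel, k_range=[2], n_iter=n_iter, distance="euclidean", seed=seed
    )
    labels = res.labels[2]
    means = sel.values.mean(axis=0, skipna=True)
    class_means = means.groupby(labels).mean()
    if abs(class_means.max() - class_means.min()) < min_separation:
        warnings.warn("no CIMP structure: class mean betas nearly equal", stacklevel=2)
    positive_class = class_means.idxmax()
    return labels.eq(positive_class).rename("cimp")
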