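"""Cluster-of-clusters integration of per-omic partitions.

Each single-omic partition is expanded into one binary indicator variable
per class (1 = sample in the class, 0 = in another class of that partition,
NA = sample not classified at that molecular level). Samples are then
consensus-clustered on the concatenated indicator rows with Pearson
dissimilarity over pairwise-complete variables, yielding an integrated
multi-omics partition. Also houses the miRNA preprocessing that feeds the
miRNA partition, and the chi-square association between partitions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .consensus import ConsensusResult, consensus_cluster
from .types import OmicsMatrix, ValidationError, validate_partition

__all__ = [
    "encode_partitions",
    "cluster_of_clusters",
    "mirna_preprocess",
    "crosstab_association",
]


def encode_partitions(partitions: list[pd.Series], names: list[str] | None = None) -> pd.DataFrame:
    """Binary indicator matrix (samples × class variables) from ≥2 partitions.

    Column blocks are named ``<partition>:<class>``; a sample missing from a
    partition gets NA on that partition's whole block.
    """
    if len(partitions) < 2:
        raise ValidationError("need at least 2 partitions to integrate")
    if names is None:
        names = [p.name or f"omic{i + 1}" for i, p in enumerate(partitions)]
    all_samples = pd.Index([])
    for p in partitions:
        validate_partition(p)
        all_samples = all_samples.union(p.index)
    blocks = []
    for name, p in zip(names, partitions):
        classes = sorted(p.dropna().unique(), key=str)
        if len(classes) < 2:
            raise ValidationError(f"partition {name!r} has a single class")
        block = pd.DataFrame(
            np.nan, index=all_samples, columns=[f"{name}:{c}" for c in classes]
        )
        labelled = p.dropna()
        for c in classes:
            block.loc[labelled.index, f"{name}:{c}"] = (labelled == c).astype(float)
        blocks.append(block)
    return pd.concat(blocks, axis=1)


def cluster_of_clusters(
    indicator: pd.DataFrame,
    k_range=range(2, 9),
    n_iter: int = 1000,
    seed: int = 0,
    delta_threshold: float = 0.10,
) -> ConsensusResult:
    """Consensus-cluster samples on their class-indicator rows.

    Samples unclassified on every omic are excluded with a warning. Returns
    the full :class:`ConsensusResult`; the integrated partition is
    ``result.selected_labels()``.
    """
    all_na = indicator.isna().all(axis=1)
    if all_na.any():
        warnings.warn(
            f"excluding {int(all_na.sum())} samples unclassified on every omic",
            stacklevel=2,
        )
        indicator = indicator.loc[~all_na]
    return consensus_cluster(
        indicator, k_range=k_range, n_iter=n_iter, distance="pearson",
        seed=seed, delta_threshold=delta_threshold,
    )


def mirna_preprocess(
    counts: pd.DataFrame,
    min_reads: int = 10,
    min_samples: int = 2,
    scale: float = 1e6,
    cpm_first: bool = False,
) -> OmicsMatrix:
    """miRNA count matrix → normalized, centred expression matrix.

    Keeps miRNAs with more than ``min_reads`` reads in at least
    ``min_samples`` samples, then (default order) log2-transforms counts
    (pseudocount 1), divides each sample's column by that sample's total
    raw read count (rescaled by ``scale`` to keep values in a friendly
    numeric range), and centres every retained miRNA on its mean.
    ``cpm_first=True`` swaps to the conventional counts-per-million-then-log2
    order instead. Samples with zero total reads are excluded with a warning.
    """
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals != np.floor(vals)):
        raise ValidationError("miRNA counts must be non-negative integers")
    totals = counts.sum(axis=0)
    dead = totals == 0
    if dead.any():
        warnings.warn(
            f"excluding {int(dead.sum())} samples with zero total reads", stacklevel=2
        )
        counts = counts.loc[:, ~dead]
        totals = totals[~dead]
    keep = (counts > min_reads).sum(axis=1) >= min_samples
    kept = counts.loc[keep]
    if cpm_first:
        x = np.log2(kept.div(totals / scale, axis=1) + 1.0)
    else:
        x = np.log2(kept + 1.0).div(totals / scale, axis=1)
    x = x.sub(x.mean(axis=1), axis=0)
    return OmicsMatrix(x, "mirna")


def crosstab_association(a: pd.Series, b: pd.Series):
    """Pearson chi-square between two partitions on co-labelled samples.

    Returns ``(table, statistic, p_value)`` where ``table`` is the
    contingency table of samples non-NA in both partitions.
    """
    shared = a.dropna().index.intersection(b.dropna().index)
    table = pd.crosstab(a.loc[shared], b.loc[shared])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(
            "degenerate contingency table: need >= 2 classes per partition "
            "on the shared samples"
        )
    stat, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
    return table, float(stat), float(p)
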