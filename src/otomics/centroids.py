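"""Cross-cohort class matching by centroid correlation.

For each dataset and class, a centroid is the per-gene mean expression over
the class members. Between two datasets, genes are restricted to those
measured in both, each dataset's most-variant fraction is recomputed on the
shared genes, and the centroids are correlated (Pearson) on the
intersection of the two selections. Hierarchical clustering of all
centroids on the 1 − r distance then groups corresponding classes across
datasets into meta-classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .consensus import select_variant_features
from .types import OmicsMatrix, ValidationError, validate_partition

__all__ = ["CentroidSet", "compute_centroids", "centroid_correlations", "match_classes"]


@dataclass
class CentroidSet:
    """Per-class mean expression profiles for one dataset.

    ``centroids`` holds class means over the dataset's selected most-variant
    genes; ``full_means`` and ``variances`` keep the all-gene class means
    and per-gene variances so pairwise comparisons can re-select genes on
    the universe shared with another dataset.
    """

    dataset_id: str
    centroids: pd.DataFrame  # selected genes × classes
    full_means: pd.DataFrame  # all genes × classes
    variances: pd.Series  # per-gene variance within the dataset
    fraction: float = 0.10

    @property
    def classes(self) -> list:
        return list(self.centroids.columns)

    @property
    def gene_universe(self) -> pd.Index:
        return self.full_means.index


def compute_centroids(
    matrix, partition: pd.Series, fraction: float = 0.10, dataset_id: str = "dataset"
) -> CentroidSet:
    """Class centroids over the dataset's top-``fraction`` most variant genes.

    Classes with zero labelled samples are dropped; permutation of sample
    order never changes the result.
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    partition = validate_partition(partition.reindex(values.columns))
    labelled = partition.dropna()
    selected = select_variant_features(values, fraction)
    means = {}
    for cls in sorted(labelled.unique(), key=str):
        members = labelled.index[labelled == cls]
        if len(members) == 0:
            continue
        means[cls] = values[members].mean(axis=1, skipna=True)
    full_means = pd.DataFrame(means)
    return CentroidSet(
        dataset_id=dataset_id,
        centroids=full_means.loc[selected],
        full_means=full_means,
        variances=values.var(axis=1, skipna=True, ddof=1),
        fraction=fraction,
    )


def _pair_gene_selection(a: CentroidSet, b: CentroidSet, min_shared: int = 10) -> pd.Index:
    shared = a.gene_universe.intersection(b.gene_universe)
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} shared genes between {a.dataset_id} and {b.dataset_id}"
        )
    if a.dataset_id == b.dataset_id:
        k = int(np.ceil(a.fraction * len(shared)))
        return a.variances.loc[shared].nlargest(k).index
    sel = []
    for cs in (a, b):
        k = int(np.ceil(cs.fraction * len(shared)))
        sel.append(set(cs.variances.loc[shared].nlargest(k).index))
    inter = pd.Index(sorted(sel[0] & sel[1]))
    if len(inter) < 3:
        warnings.warn(
            "top-variant selections barely overlap; falling back to their union",
            stacklevel=2,
        )
        inter = pd.Index(sorted(sel[0] | sel[1]))
    return inter


def centroid_correlations(a: CentroidSet, b: CentroidSet) -> pd.DataFrame:
    """Class × class Pearson correlation matrix between two centroid sets."""
    genes = _pair_gene_selection(a, b)
    ca = a.full_means.loc[genes]
    cb = b.full_means.loc[genes]
    out = pd.DataFrame(index=ca.columns, columns=cb.columns, dtype=float)
    for i in ca.columns:
        for j in cb.columns:
            out.loc[i, j] = np.corrcoef(ca[i], cb[j])[0, 1]
    return out


def match_classes(
    sets: list[CentroidSet], n_meta: int = 3, linkage_method: str = "average"
) -> pd.DataFrame:
    """Group class centroids from >= 2 datasets into meta-classes.

    Builds the full centroid × centroid 1 − r distance matrix (each pair
    correlated on that pair's shared-gene selection, so gene universes mix
    across pairs), clusters it hierarchically and cuts into ``n_meta``
    groups. Returns a frame with columns dataset, class, meta_class. A
    warning is raised if some meta-class lacks a member from some dataset.
    """
    if len(sets) < 2:
        raise ValidationError("need >= 2 centroid sets")
    members = [(cs, cls) for cs in sets for cls in cs.classes]
    total = len(members)
    if n_meta > total:
        raise ValidationError(f"n_meta={n_meta} exceeds {total} classes")
    D = np.zeros((total, total))
    cache: dict[tuple[str, str], pd.DataFrame] = {}
    for i, (csa, ca) in enumerate(members):
        for j in range(i + 1, total):
            csb, cb = members[j]
            key = (csa.dataset_id, csb.dataset_id)
            if key not in cache:
                cache[key] = centroid_correlations(csa, csb)
            r = cache[key].loc[ca, cb]
            D[i, j] = D[j, i] = 1.0 - r
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    meta = fcluster(Z, t=n_meta, criterion="maxclust")
    out = pd.DataFrame(
        {
            "dataset": [cs.dataset_id for cs, _ in members],
            "class": [cls for _, cls in members],
            "meta_class": meta,
        }
    )
    datasets = {cs.dataset_id for cs in sets}
    for m, sub in out.groupby("meta_class"):
        missing = datasets - set(sub["dataset"])
        if missing:
            warnings.warn(
                f"meta-class {m} lacks members from {sorted(missing)}", stacklevel=2
            )
    return out


def nearest_centroid(matrix, centroid_set: CentroidSet) -> pd.Series:
    # helper for tests: assign each sample to the most correlated centroid
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    genes = centroid_set.centroids.index.intersection(values.index)
    sub = values.loc[genes]
    cen = centroid_set.centroids.loc[genes]
    labels = {}
    for s in sub.columns:
        r = cen.apply(lambda c: np.corrcoef(c, sub[s])[0, 1])
        labels[s] = r.idxmax()
    return pd.Series(labels)
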