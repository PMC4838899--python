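"""Resampled consensus clustering with CDF-area model selection.

The engine repeats hierarchical clustering on random subsamples of the
cohort and records, for every sample pair, the fraction of co-sampled
iterations in which the pair landed in the same cluster. The resulting
consensus matrix M_K (one per candidate K) is near-binary when K matches the
real group structure; the area under the empirical CDF of its off-diagonal
entries grows as K approaches the true number of groups and plateaus beyond
it. K is selected as the largest K whose relative area increase
Δ(K) = (A(K) − A(K−1)) / A(K−1) still exceeds a threshold (default 0.10);
the full Δ curve is kept so the automatic choice can be overridden.

Distances: Pearson dissimilarity (1 − r over features, pairwise-complete
when NA are present) or Euclidean (NaN-aware). Linkage is Ward in two
variants: ``"D2"`` applies the classic Lance–Williams Ward recurrence to
squared input dissimilarities (scipy's ``ward`` on d), ``"D"`` applies it to
the dissimilarities as given, matching R's ``hclust(..., "ward.D")``
(equivalently scipy's ``ward`` on sqrt(d); tree identical up to a monotone
height transform). Pearson mode defaults to "D2", Euclidean mode to "D".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

from .types import OmicsMatrix, ValidationError

__all__ = [
    "ConsensusResult",
    "select_variant_features",
    "consensus_cluster",
    "cdf_area",
    "select_k",
    "flag_contamination",
]


def select_variant_features(matrix, fraction: float) -> list[str]:
    """Ids of the ``ceil(fraction * n_features)`` most variant features.

    Variance is computed per feature over non-NA entries, on the values as
    provided (no re-centring). All-NA features are excluded before ranking;
    ties break lexicographically by feature id.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    n = values.shape[0]
    var = values.var(axis=1, skipna=True, ddof=1)
    var = var.dropna()
    k = int(np.ceil(fraction * n))
    order = var.to_frame("var").reset_index(names="feature")
    order = order.sort_values(["var", "feature"], ascending=[False, True])
    return order["feature"].head(k).tolist()


def pearson_dissimilarity(data: pd.DataFrame) -> np.ndarray:
    """1 − Pearson r between item rows of ``data`` (items × features).

    Pairwise-complete when NA are present; pairs with fewer than 3 shared
    features (or zero variance) get an undefined dissimilarity which is
    imputed as the row maximum, keeping the linkage total.
    """
    X = data.to_numpy(dtype=float)
    if not np.isnan(X).any():
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(X)
    else:
        r = data.T.corr(min_periods=3).to_numpy()
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = _impute_undefined(d)
    return (d + d.T) / 2.0


def euclidean_dissimilarity(data: pd.DataFrame) -> np.ndarray:
    X = data.to_numpy(dtype=float)
    if not np.isnan(X).any():
        return squareform(pdist(X, metric="euclidean"))
    d = nan_euclidean_distances(X)
    np.fill_diagonal(d, 0.0)
    d = _impute_undefined(d)
    return (d + d.T) / 2.0


def _impute_undefined(d: np.ndarray) -> np.ndarray:
    if np.isnan(d).any():
        rowmax = np.nanmax(np.where(np.isnan(d), -np.inf, d), axis=1)
        fallback = np.nanmax(rowmax)
        fill = np.maximum.outer(rowmax, rowmax)
        d = np.where(np.isnan(d), np.where(np.isfinite(fill), fill, fallback), d)
    return d


_DISTANCES = {"pearson": pearson_dissimilarity, "euclidean": euclidean_dissimilarity}


def _ward_linkage(condensed: np.ndarray, variant: str) -> np.ndarray:
    condensed = np.maximum(condensed, 0.0)
    if variant == "D":
        return linkage(np.sqrt(condensed), method="ward")
    if variant == "D2":
        return linkage(condensed, method="ward")
    raise ValidationError(f"unknown Ward variant {variant!r}")


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, CDF areas, labels and the selected K."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]
    areas: dict[int, float]
    deltas: dict[int, float]
    labels: dict[int, pd.Series]
    selected_k: int
    weak_structure: bool = False
    item_consensus: dict[int, pd.Series] = field(default_factory=dict)

    def selected_labels(self) -> pd.Series:
        return self.labels[self.selected_k]


def consensus_cluster(
    matrix,
    k_range=range(2, 9),
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    distance: str = "pearson",
    linkage_variant: str | None = None,
    seed: int = 0,
    delta_threshold: float = 0.10,
) -> ConsensusResult:
    """Consensus clustering of samples by resampled hierarchical clustering.

    ``matrix`` is an :class:`OmicsMatrix` (items = samples, feature vectors
    = columns) or an items × features ``DataFrame``. Samples (items) are
    subsampled without replacement at ``subsample_fraction`` per iteration;
    the pairwise item dissimilarity is computed once on the full data and
    restricted to each subsample (features are never subsampled, so the
    restriction is exact). ``seed`` fixes the resampling exactly.
    """
    if isinstance(matrix, OmicsMatrix):
        data = matrix.values.T
    else:
        data = matrix
    items = data.index
    n = len(items)
    k_range = [int(k) for k in k_range]
    if not k_range or max(k_range) > n:
        raise ValidationError(f"k_range {k_range} incompatible with {n} items")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if distance not in _DISTANCES:
        raise ValidationError(f"distance must be one of {sorted(_DISTANCES)}")
    if linkage_variant is None:
        linkage_variant = "D2" if distance == "pearson" else "D"

    D = _DISTANCES[distance](data)
    rng = np.random.default_rng(seed)
    m = max(max(k_range), int(round(subsample_fraction * n)))
    m = min(m, n)

    co = {k: np.zeros((n, n)) for k in k_range}
    tog = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = D[np.ix_(idx, idx)]
        Z = _ward_linkage(squareform(sub, checks=False), linkage_variant)
        ix = np.ix_(idx, idx)
        tog[ix] += 1.0
        for k in k_range:
            lab = fcluster(Z, t=k, criterion="maxclust")
            co[k][ix] += lab[:, None] == lab[None, :]

    with np.errstate(invalid="ignore"):
        M = {k: co[k] / tog for k in k_range}
    never = ~np.isfinite(tog) | (tog == 0)
    np.fill_diagonal(never, False)
    frac_na = never.sum() / max(n * (n - 1), 1)
    if frac_na > 0.01:
        warnings.warn(
            f"{frac_na:.1%} of sample pairs were never co-sampled; "
            "consensus entries for them are NA", stacklevel=2,
        )

    consensus, areas, labels, item_cons = {}, {}, {}, {}
    for k in k_range:
        Mk = M[k]
        np.fill_diagonal(Mk, 1.0)
        Mk_df = pd.DataFrame(Mk, index=items, columns=items)
        consensus[k] = Mk_df
        areas[k] = cdf_area(Mk_df)
        dk = 1.0 - Mk
        dk = _impute_undefined(dk)
        np.fill_diagonal(dk, 0.0)
        Zk = _ward_linkage(squareform((dk + dk.T) / 2.0, checks=False), linkage_variant)
        lab = fcluster(Zk, t=k, criterion="maxclust")
        lab_s = pd.Series(lab, index=items, name=f"K{k}")
        labels[k] = lab_s
        item_cons[k] = _item_consensus(Mk_df, lab_s)

    if len(k_range) >= 2:
        selected, deltas, weak = select_k(areas, delta_threshold=delta_threshold, full=True)
    else:
        selected, deltas, weak = k_range[0], {k_range[0]: areas[k_range[0]]}, False
    return ConsensusResult(
        k_range=k_range, consensus=consensus, areas=areas, deltas=deltas,
        labels=labels, selected_k=selected, weak_structure=weak,
        item_consensus=item_cons,
    )


def _item_consensus(Mk: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Mean consensus of each item with the other members of its cluster."""
    vals = Mk.to_numpy()
    out = np.full(len(labels), np.nan)
    lab = labels.to_numpy()
    for c in np.unique(lab):
        mask = lab == c
        if mask.sum() < 2:
            out[mask] = 1.0
            continue
        block = vals[np.ix_(mask, mask)]
        out[mask] = (np.nansum(block, axis=1) - 1.0) / (mask.sum() - 1)
    return pd.Series(out, index=labels.index)


def cdf_area(consensus_matrix) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries on [0,1]."""
    M = np.asarray(consensus_matrix, dtype=float)
    iu = np.triu_indices_from(M, k=1)
    v = M[iu]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no defined off-diagonal consensus entries")
    v = np.sort(v)
    xs = np.concatenate((v, [1.0]))
    F = np.arange(1, v.size + 1) / v.size
    return float(np.sum((xs[1:] - xs[:-1]) * F))


def select_k(areas: dict[int, float], delta_threshold: float = 0.10, full: bool = False):
    """Largest K whose relative CDF-area increase Δ(K) meets the threshold.

    Δ(k_min) = A(k_min); for later K, Δ(K) = (A(K) − A(K−1)) / A(K−1).
    When no K beyond k_min qualifies the selection falls back to k_min and
    the result is flagged as weak structure.
    """
    ks = sorted(areas)
    if len(ks) < 2:
        raise ValidationError("need at least two K values to select from")
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        a_prev = areas[prev]
        deltas[k] = (areas[k] - a_prev) / a_prev if a_prev > 0 else np.inf
    qualifying = [k for k in ks if deltas[k] >= delta_threshold]
    weak = False
    if qualifying:
        selected = max(qualifying)
        if selected == ks[0]:
            weak = True
    else:
        selected = ks[0]
        weak = True
    if weak:
        warnings.warn(
            f"weak cluster structure: no K > {ks[0]} reaches "
            f"delta >= {delta_threshold}", stacklevel=2,
        )
    if full:
        return selected, deltas, weak
    return selected


def flag_contamination(partition: pd.Series, annot: pd.DataFrame) -> list[str]:
    """Tumour samples clustering with the normal controls.

    Any class containing at least half of all normal-control samples is
    treated as the normal-like class; every tumour sample in such a class is
    flagged for removal from downstream matrices.
    """
    if "is_normal_control" not in annot.columns:
        raise ValidationError("annot lacks is_normal_control column")
    controls = annot.index[annot["is_normal_control"].fillna(False).astype(bool)]
    controls = controls.intersection(partition.dropna().index)
    if len(controls) == 0:
        warnings.warn("no normal controls present; nothing flagged", stacklevel=2)
        return []
    counts = partition.loc[controls].value_counts()
    flagged: list[str] = []
    for cls, cnt in counts.items():
        if cnt / len(controls) >= 0.5:
            members = partition.index[partition == cls]
            flagged.extend(s for s in members if s not in set(controls))
    return sorted(flagged)
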