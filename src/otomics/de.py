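"""Moderated-t differential expression, signatures, enrichment, MYC score.

The moderated t-statistic shrinks per-gene residual variances toward a
common prior fitted by empirical Bayes: per-gene sample variances s² with d
degrees of freedom are modelled as s² ~ s0²·F(d, d0); the prior (d0, s0²)
is estimated by matching the first two moments of log s² to the scaled-F
distribution (digamma/trigamma moment equations, with the trigamma inverse
solved by Newton iteration). The posterior variance
s̃² = (d0·s0² + d·s²) / (d0 + d) then yields t̃ = lfc / (s̃·√(1/n1 + 1/n2))
on d0 + d degrees of freedom. d0 = 0 recovers the ordinary equal-variance
two-sample t; d0 → ∞ pins every gene's variance at s0².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import hypergeom
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .types import GeneSet, OmicsMatrix, ValidationError

__all__ = [
    "DEResult",
    "moderated_t",
    "signature_top_n",
    "hypergeom_enrich",
    "myc_activity_score",
    "trigamma_inverse",
]


@dataclass
class DEResult:
    """Per-feature differential expression with the fitted variance prior."""

    table: pd.DataFrame  # columns: lfc, t, p, df, padj (optional)
    d0: float
    s02: float

    def __post_init__(self) -> None:
        p = self.table["p"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p-values outside [0,1]")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log s² to log(s0² · F(df, d0)); returns (d0, s0²)."""
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (e.size - 1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def moderated_t(
    matrix,
    group,
    prior_df: float | None = None,
    prior_var: float | None = None,
    adjust: bool = False,
) -> DEResult:
    """Empirical-Bayes moderated two-sample t-test per feature.

    ``group`` is a boolean (or two-level) label per sample: the log fold
    change is mean(group) − mean(rest). ``prior_df``/``prior_var`` override
    the fitted prior (diagnostic limit cases); ``adjust=True`` adds a
    Benjamini–Hochberg column. Features with zero variance in both groups
    get p = NA.
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    g = pd.Series(group)
    g = g.reindex(values.columns)
    if g.isna().any():
        keep = g.dropna().index
        values, g = values[keep], g.loc[keep]
    levels = pd.unique(g)
    if len(levels) != 2:
        if g.dtype == bool or set(levels) <= {0, 1, True, False}:
            g = g.astype(bool)
        else:
            raise ValidationError("group must be binary")
    else:
        g = g == levels[0] if g.dtype != bool else g
    in1 = g.to_numpy(dtype=bool)
    X = values.to_numpy(dtype=float)
    X1, X0 = X[:, in1], X[:, ~in1]
    n1 = np.sum(~np.isnan(X1), axis=1)
    n0 = np.sum(~np.isnan(X0), axis=1)
    if (n1 < 2).all() or (n0 < 2).all():
        raise ValidationError("need >= 2 samples per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(X1, axis=1)
        m0 = np.nanmean(X0, axis=1)
        v1 = np.nanvar(X1, axis=1, ddof=1)
        v0 = np.nanvar(X0, axis=1, ddof=1)
    lfc = m1 - m0
    d = n1 + n0 - 2.0
    s2 = ((n1 - 1) * np.nan_to_num(v1) + (n0 - 1) * np.nan_to_num(v0)) / np.where(d > 0, d, np.nan)

    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, d)
    else:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else _fit_f_dist(s2, d)[1]

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    # a feature constant within both groups carries no evidence either way
    bad = ~np.isfinite(t) | (d <= 0) | (s2 == 0)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)

    table = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "df": np.where(bad, np.nan, df_total)},
        index=values.index,
    )
    if adjust:
        mask = table["p"].notna()
        padj = pd.Series(np.nan, index=table.index)
        if mask.any():
            padj[mask] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
        table["padj"] = padj
    return DEResult(table, d0=d0, s02=s02)


def signature_top_n(de: DEResult, n: int = 100, alpha: float = 0.05) -> list[str]:
    """Top-n up-regulated features by fold change among those with p < alpha.

    Ranking uses the unadjusted p-value (no multiple-testing correction)
    and positive lfc only; descending lfc, ties broken by feature id.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    tab = de.table
    sig = tab[(tab["p"] < alpha) & (tab["lfc"] > 0)].copy()
    if sig.empty:
        warnings.warn("no significantly up-regulated features", stacklevel=2)
        return []
    sig = sig.reset_index(names="feature").sort_values(
        ["lfc", "feature"], ascending=[False, True]
    )
    if len(sig) < n:
        warnings.warn(
            f"only {len(sig)} significant up-regulated features (< {n})", stacklevel=2
        )
    return sig["feature"].head(n).tolist()


def hypergeom_enrich(signature, gene_set: GeneSet, universe) -> tuple[float, int]:
    """Upper-tail hypergeometric enrichment p-value, P[X >= overlap].

    ``signature`` must be a subset of ``universe``; the gene set is
    intersected with the universe. Returns ``(p, overlap)``.
    """
    universe = set(universe)
    signature = set(signature)
    if not universe or not len(gene_set):
        raise ValidationError("empty universe or gene set")
    if not signature <= universe:
        raise ValidationError("signature must be a subset of the universe")
    members = set(gene_set) & universe
    k = len(signature & members)
    M, K, N = len(universe), len(members), len(signature)
    p = float(hypergeom.sf(k - 1, M, K, N))
    return p, k


def myc_activity_score(
    matrix,
    myc_targets: GeneSet,
    centred: bool = True,
    centre_on: str = "genes",
):
    """Per-sample MYC activity: mean expression of MYC target genes.

    ``centred`` subtracts, per gene, the cohort mean before averaging
    (``centre_on="samples"`` instead subtracts each sample's own mean over
    all genes). Returns ``(scores, missing_targets)``.
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    present = [g for g in myc_targets if g in values.index]
    missing = [g for g in myc_targets if g not in values.index]
    if not present:
        raise ValidationError(f"no MYC targets present (set {myc_targets.name!r})")
    x = values
    if centred:
        if centre_on == "genes":
            x = x.sub(x.mean(axis=1), axis=0)
        elif centre_on == "samples":
            x = x.sub(x.mean(axis=0), axis=1)
        else:
            raise ValidationError("centre_on must be 'genes' or 'samples'")
    scores = x.loc[present].mean(axis=0, skipna=True).rename("myc_score")
    return scores, missing
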