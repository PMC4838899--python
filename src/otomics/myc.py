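"""MYC deregulation: per-sample event aggregation and exclusivity testing.

Four events can each push MYC activity up: MYC locus genomic gain, MAX
locus genomic loss, MYC exon 3 hypomethylation, and mir34b/c promoter
hypermethylation (silencing two MYC-repressing microRNAs). The event table
aggregates them per sample; the exclusivity test asks whether two event
types co-occur less often than expected under independence, via a one-sided
binomial test on the co-occurrence count with null rate pA·pB from the
observed marginals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom, ttest_ind

from .types import ValidationError

__all__ = ["aggregate_events", "exclusivity_test", "score_by_event", "EVENT_COLUMNS"]

EVENT_COLUMNS = ["myc_gain", "max_loss", "myc_hypometh", "mir34_hypermeth"]


def aggregate_events(
    myc_gain: pd.Series,
    max_loss: pd.Series,
    myc_hypometh: pd.Series,
    mir34_hypermeth: pd.Series,
    myc_score: pd.Series | None = None,
) -> pd.DataFrame:
    """Combine the four MYC-event call vectors into one event table.

    All calls must cover the same sample universe. ``any_event`` is the OR
    over non-NA events; rows where all four are NA get NA.
    """
    calls = [myc_gain, max_loss, myc_hypometh, mir34_hypermeth]
    idx = calls[0].index
    for c in calls[1:]:
        if set(c.index) != set(idx):
            raise ValidationError("event call vectors cover different sample sets")
    table = pd.DataFrame(
        {name: c.reindex(idx) for name, c in zip(EVENT_COLUMNS, calls)}
    )
    ev = table[EVENT_COLUMNS]
    any_true = ev.eq(True).any(axis=1)
    all_na = ev.isna().all(axis=1)
    table["any_event"] = np.where(all_na, np.nan, any_true)
    if myc_score is not None:
        table["myc_score"] = myc_score.reindex(idx)
    return table


def exclusivity_test(event_a: pd.Series, event_b: pd.Series) -> dict:
    """One-sided binomial test for mutual exclusivity of two event types.

    On samples where both calls are non-NA, with marginal rates pA and pB,
    the co-occurrence count k is compared to Binomial(n, pA·pB):
    p = P[X <= k] (small p = fewer co-occurrences than independence
    predicts). Degenerate marginals (pA or pB = 0) give p = 1 with a note.
    """
    a = event_a.astype(object)
    b = event_b.reindex(event_a.index).astype(object)
    mask = a.notna() & b.notna()
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("no samples with both events called")
    av = a[mask].astype(bool).to_numpy()
    bv = b[mask].astype(bool).to_numpy()
    pa, pb = av.mean(), bv.mean()
    k = int((av & bv).sum())
    result = {
        "n": n,
        "k": k,
        "p_a": float(pa),
        "p_b": float(pb),
        "expected": float(n * pa * pb),
    }
    if pa == 0 or pb == 0:
        result["p"] = 1.0
        result["note"] = "a marginal rate is zero; no power"
        return result
    result["p"] = float(binom.cdf(k, n, pa * pb))
    return result


def score_by_event(etable: pd.DataFrame, scores: pd.Series | None = None) -> dict:
    """MYC activity by event status: quartile summaries and a Welch t-test.

    Groups samples by ``any_event``; requires >= 2 samples in each of the
    with-event and without-event groups.
    """
    if scores is None:
        if "myc_score" not in etable.columns:
            raise ValidationError("no myc_score column and no scores given")
        scores = etable["myc_score"]
    scores = scores.reindex(etable.index)
    status = etable["any_event"]
    mask = status.notna() & scores.notna()
    grp = status[mask].astype(bool)
    x1 = scores[mask][grp].to_numpy(dtype=float)
    x0 = scores[mask][~grp].to_numpy(dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise ValidationError("need >= 2 samples per event group")

    def _summary(x):
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"n": len(x), "q1": float(q1), "median": float(med), "q3": float(q3)}

    t, p = ttest_ind(x1, x0, equal_var=False)
    return {
        "with_event": _summary(x1),
        "without_event": _summary(x0),
        "t": float(t),
        "p": float(p),
    }
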