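"""Kaplan–Meier estimation, log-rank tests, cohort pooling, RT stratification.

Times are in months throughout. The product-limit estimator and the
(unstratified) log-rank test are delegated to lifelines; the cohort-
stratified log-rank variant sums per-stratum observed-minus-expected event
counts and variances before forming the chi-square statistic.

The radiotherapy analysis applies the landmark rule used for treatment
comparisons: patients deceased within the first 3 months are excluded (they
could not have effectively received radiotherapy) and follow-up is
administratively censored at a 5-year horizon.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2

from .types import ValidationError

__all__ = ["km_estimate", "logrank", "pooled_survival", "rt_stratified"]


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a frame with columns ``time``, ``at_risk``,
    ``n_events`` and ``survival``. Deaths are processed before censorings at
    tied times (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "n_events": tab["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(tab.index).to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def logrank(groups) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups of ``(times, events)`` pairs.

    Empty groups are dropped with a warning. Returns
    ``(chi2_statistic, degrees_of_freedom, p_value)``.
    """
    kept = [(np.asarray(t, float), np.asarray(e, int)) for t, e in groups]
    nonempty = [(t, e) for t, e in kept if t.size > 0]
    if len(nonempty) < len(kept):
        warnings.warn("dropping empty survival group(s)", stacklevel=2)
    if len(nonempty) < 2:
        raise ValidationError("need >= 2 non-empty groups")
    if sum(int(e.sum()) for _, e in nonempty) < 1:
        raise ValidationError("need >= 1 event overall")
    durations = np.concatenate([t for t, _ in nonempty])
    observed = np.concatenate([e for _, e in nonempty])
    labels = np.concatenate(
        [np.full(t.size, i) for i, (t, _) in enumerate(nonempty)]
    )
    res = multivariate_logrank_test(durations, labels, observed)
    return float(res.test_statistic), len(nonempty) - 1, float(res.p_value)


def _logrank_oe(times, events, in_group) -> tuple[float, float]:
    """Observed-minus-expected events and variance for one 2-group stratum."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_group = np.asarray(in_group, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


def stratified_logrank(records: pd.DataFrame, group_col: str, strata_col: str):
    """Two-group log-rank stratified on ``strata_col`` (O−E and V summed)."""
    groups = records[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValidationError("stratified log-rank supports exactly 2 groups")
    ref = groups[0]
    oe, var = 0.0, 0.0
    for _, sub in records.groupby(strata_col):
        if sub[group_col].nunique() < 2:
            continue
        o, v = _logrank_oe(sub["os_time"], sub["os_event"], sub[group_col] == ref)
        oe += o
        var += v
    if var == 0:
        raise ValidationError("no informative stratum for stratified log-rank")
    stat = oe**2 / var
    return float(stat), 1, float(chi2.sf(stat, 1))


def pooled_survival(cohorts, group_rule=None) -> dict:
    """Pool survival records across cohorts and compare groups by log-rank.

    ``cohorts`` is a list of ``(cohort_name, records)`` where ``records``
    has columns ``os_time``, ``os_event`` and ``group`` (or a column from
    which ``group_rule(row) -> label`` derives it). Reports the unstratified
    log-rank (default reading) and, when exactly two groups are present, the
    cohort-stratified variant as well.
    """
    frames = []
    for name, rec in cohorts:
        rec = rec.copy()
        if group_rule is not None:
            rec["group"] = rec.apply(group_rule, axis=1)
        rec["cohort"] = name
        frames.append(rec[["os_time", "os_event", "group", "cohort"]])
    pooled = pd.concat(frames, ignore_index=True).dropna(
        subset=["os_time", "os_event", "group"]
    )
    if pooled.empty:
        raise ValidationError("no usable pooled records")
    groups = [
        (sub["os_time"].to_numpy(), sub["os_event"].to_numpy())
        for _, sub in pooled.groupby("group")
    ]
    stat, df, p = logrank(groups)
    out = {
        "n": len(pooled),
        "statistic": stat,
        "df": df,
        "p": p,
        "records": pooled,
    }
    if pooled["group"].nunique() == 2 and pooled["cohort"].nunique() > 1:
        try:
            s_stat, _, s_p = stratified_logrank(pooled, "group", "cohort")
            out["stratified_statistic"] = s_stat
            out["stratified_p"] = s_p
        except ValidationError:
            pass
    return out


def rt_stratified(
    records: pd.DataFrame,
    horizon_months: float = 60.0,
    landmark_months: float = 3.0,
    subtype_col: str = "subtype",
) -> pd.DataFrame:
    """Within-subtype comparison of initial radiotherapy vs none.

    ``records`` needs ``os_time``, ``os_event``, ``initial_radiotherapy``
    and a subtype column. Patients deceased before ``landmark_months`` are
    excluded; all follow-up is censored at ``horizon_months``. Strata with
    fewer than 2 patients in either arm get NA with a note.
    """
    rec = records.dropna(
        subset=["os_time", "os_event", "initial_radiotherapy", subtype_col]
    ).copy()
    early_death = (rec["os_event"].astype(int) == 1) & (
        rec["os_time"] < landmark_months
    )
    rec = rec[~early_death]
    over = rec["os_time"] > horizon_months
    rec.loc[over, "os_event"] = 0
    rec.loc[over, "os_time"] = horizon_months

    rows = []
    for subtype, sub in rec.groupby(subtype_col):
        rt = sub["initial_radiotherapy"].astype(bool)
        n_rt, n_nort = int(rt.sum()), int((~rt).sum())
        row = {"subtype": subtype, "n_rt": n_rt, "n_no_rt": n_nort}
        if min(n_rt, n_nort) < 2:
            row.update(statistic=np.nan, p=np.nan, note="arm with < 2 patients")
        else:
            try:
                stat, _, p = logrank(
                    [
                        (sub.loc[rt, "os_time"], sub.loc[rt, "os_event"]),
                        (sub.loc[~rt, "os_time"], sub.loc[~rt, "os_event"]),
                    ]
                )
                row.update(statistic=stat, p=p, note="")
            except ValidationError as exc:
                row.update(statistic=np.nan, p=np.nan, note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtype")
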