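"""Kaplan-Meier estimation, follow-up truncation, and log-rank tests.

Follow-up is truncated at 1000 days by default (times beyond the limit
become right-censored at the limit).  KM estimation goes through
lifelines; the log-rank statistic is computed directly from the textbook
observed/expected tabulation with hypergeometric variance so that
per-group observed and expected event counts are part of the result
(lifelines serves as an independent cross-check in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io_formats import ClinicalRecord

__all__ = [
    "KmCurve",
    "LogRankResult",
    "truncate_followup",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
]


@dataclass
class KmCurve:
    """Product-limit survival curve (step function over event times)."""

    times: np.ndarray  # distinct observed times (events and censorings)
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) just after each time
    censor_times: np.ndarray  # times with censorings (plot marks)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: pd.Series  # events per group
    expected: pd.Series


def truncate_followup(records, limit: float = 1000.0) -> list:
    """Cap follow-up: times > limit become (limit, censored)."""
    out = []
    for r in records:
        if r.time > limit:
            out.append(replace(r, time=float(limit), event=0))
        else:
            out.append(r)
    return out


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate (deaths before censorings at ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    table = table[table["removed"] > 0]  # drop the synthetic t=0 anchor row
    tvals = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.reindex(table.index)["KM_estimate"].to_numpy()
    return KmCurve(
        times=tvals,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        survival=surv,
        censor_times=np.unique(times[events == 0]),
    )


def _logrank_tabulate(times, events, groups):
    """Observed/expected per group and the covariance of (O - E)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    G = len(levels)
    gi = np.array([levels.index(g) for g in groups])

    observed = np.zeros(G)
    expected = np.zeros(G)
    cov = np.zeros((G, G))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        if n <= 1:
            continue
        n_g = np.array([(at_risk & (gi == j)).sum() for j in range(G)])
        d_g = np.array([((times == t) & (events == 1) & (gi == j)).sum()
                        for j in range(G)])
        observed += d_g
        expected += d * n_g / n
        frac = n_g / n
        mult = d * (n - d) / (n - 1)
        cov += mult * (np.diag(frac) - np.outer(frac, frac))
    return levels, observed, expected, cov


def logrank_test(times, events, groups) -> LogRankResult:
    """G-group log-rank chi-square test (df = G - 1).

    Statistic: (O - E)' V^{-1} (O - E) over the first G-1 groups, with V
    the hypergeometric covariance summed over event times.
    """
    levels, observed, expected, cov = _logrank_tabulate(times, events, groups)
    counts = pd.Series(groups).value_counts()
    if (counts == 0).any() or len(levels) < 2:
        raise ValueError("every group needs >=1 subject and >=2 groups")
    G = len(levels)
    u = (observed - expected)[: G - 1]
    V = cov[: G - 1, : G - 1]
    if np.allclose(V, 0):
        statistic = 0.0
    else:
        statistic = float(u @ np.linalg.pinv(V) @ u)
    statistic = max(statistic, 0.0)
    df = G - 1
    return LogRankResult(
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0,
        observed=pd.Series(observed, index=levels),
        expected=pd.Series(expected, index=levels),
    )


def pairwise_logrank(records, labels: dict, pairs=None,
                     truncate: float = None) -> pd.DataFrame:
    """Log-rank over each cluster pair (e.g. CL2/CL3, CL2/CL4, CL3/CL4).

    ``records``: ClinicalRecords; ``labels``: sample -> group label;
    ``pairs``: iterable of (a, b) label pairs, default all pairs.
    """
    if truncate is not None:
        records = truncate_followup(records, truncate)
    recs = [r for r in records if r.sample_id in labels]
    df = pd.DataFrame({
        "time": [r.time for r in recs],
        "event": [r.event for r in recs],
        "group": [labels[r.sample_id] for r in recs],
    })
    levels = sorted(df["group"].unique().tolist())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    rows = []
    for a, b in pairs:
        sub = df[df["group"].isin([a, b])]
        res = logrank_test(sub["time"], sub["event"], sub["group"])
        rows.append({
            "group_a": a, "group_b": b,
            "statistic": res.statistic, "p": res.p_value,
            "observed_a": float(res.observed[a]),
            "expected_a": float(res.expected[a]),
            "observed_b": float(res.observed[b]),
            "expected_b": float(res.expected[b]),
        })
    return pd.DataFrame(rows)
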