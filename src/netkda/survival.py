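"""Kaplan-Meier estimation and the two-group log-rank test, from scratch.

Implements the product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)
over distinct event times, and the standard log-rank test whose statistic
compares observed events in one group with their hypergeometric expectation
at each event time.  Ties between events and censorings at the same time
follow the usual convention: events precede censorings, i.e. a record
censored at t is still at risk for events at t.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SURVIVAL_COLUMNS = ["sample", "time", "event", "arm", "group"]


class DegenerateTestError(ValueError):
    """Log-rank variance is zero: the test statistic is undefined."""


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read per-sample survival records: sample, time, event [, arm, group]."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    _validate_times_events(df["time"].to_numpy(), df["event"].to_numpy())
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate_times_events(times: np.ndarray, events: np.ndarray) -> None:
    if len(times) == 0:
        raise ValueError("need at least one survival record")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("survival times must be positive finite reals")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 (censored) or 1 (event)")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray      # distinct event times, ascending
    at_risk: np.ndarray    # n_i just before each event time
    events: np.ndarray     # d_i at each event time
    survival: np.ndarray   # S(t_i) after each event time

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S = 1 before the first event."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    @property
    def median(self) -> float:
        """First time with S(t) <= 0.5; NaN when never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.events, "survival": self.survival})


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate from times and 0/1 event indicators.

    Censored records leave the risk set after their time point (they count
    as at risk for events at exactly their own time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    _validate_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order].astype(bool)
    n = len(t_sorted)

    ev_times = np.unique(t_sorted[e_sorted])
    at_risk = np.empty(len(ev_times), dtype=np.int64)
    d = np.empty(len(ev_times), dtype=np.int64)
    surv = np.empty(len(ev_times))
    s = 1.0
    for i, t in enumerate(ev_times):
        at_risk[i] = int(np.sum(t_sorted >= t))
        d[i] = int(np.sum(e_sorted & (t_sorted == t)))
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KMCurve(times=ev_times, at_risk=at_risk, events=d, survival=surv)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    n_a: int
    n_b: int
    n_events: int


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-sample log-rank test.

    At each distinct event time with d events and n at risk (n_a in group
    A), observed events in A are compared with expectation e = d*n_a/n and
    variance v = d*(n_a/n)*(1-n_a/n)*(n-d)/(n-1); the statistic
    (sum(o-e))^2 / sum(v) is referred to chi-square with 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b)
    _validate_times_events(ta, ea)
    _validate_times_events(tb, eb)
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb]).astype(bool)
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    if not e_all.any():
        raise ValueError("log-rank test requires at least one event")

    ev_times = np.unique(t_all[e_all])
    o_minus_e = 0.0
    var = 0.0
    for t in ev_times:
        at_risk = t_all >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        died = e_all & (t_all == t)
        d = int(died.sum())
        o_a = int((died & in_a).sum())
        o_minus_e += o_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0.0:
        raise DegenerateTestError("zero log-rank variance (no informative event time)")
    chi2 = o_minus_e * o_minus_e / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi_square=float(chi2), p_value=p,
                         n_a=len(ta), n_b=len(tb), n_events=int(e_all.sum()))


def compare_groups(
    records: pd.DataFrame,
    by: str = "arm",
    within: str | None = None,
) -> pd.DataFrame:
    """Pairwise log-rank comparisons of ``by`` levels, optionally per ``within`` stratum.

    Returns one row per comparison: stratum (if any), group_a, group_b,
    n_a, n_b, events, chi_square, p.  Degenerate comparisons (a level with
    no records, or zero variance) are skipped.
    """
    rows = []
    strata = [None] if within is None else sorted(records[within].dropna().unique())
    for stratum in strata:
        sub = records if stratum is None else records[records[within] == stratum]
        levels = sorted(sub[by].dropna().unique())
        for i, ga in enumerate(levels):
            for gb in levels[i + 1:]:
                ra = sub[sub[by] == ga]
                rb = sub[sub[by] == gb]
                if ra.empty or rb.empty:
                    continue
                try:
                    res = logrank_test(ra["time"], ra["event"],
                                       rb["time"], rb["event"])
                except (ValueError, DegenerateTestError):
                    continue
                row = {"group_a": str(ga), "group_b": str(gb),
                       "n_a": res.n_a, "n_b": res.n_b,
                       "events": res.n_events,
                       "chi_square": res.chi_square, "p": res.p_value}
                if within is not None:
                    row = {"stratum": str(stratum), **row}
                rows.append(row)
    return pd.DataFrame(rows)
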