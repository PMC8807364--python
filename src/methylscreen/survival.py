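"""Survival statistics: median split, Kaplan-Meier, two-group log-rank.

Implemented from first principles (the point of this module), with the
standard conventions:

* Median split: subjects with marker strictly above the median are "high",
  ties go to "low", so with an even tie-free cohort the groups are equal.
* Product-limit estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i) over
  distinct event times t_i with d_i events among n_i at risk; subjects
  censored exactly at an event time still count as at risk there.
* Log-rank: at each distinct event time with d events, n at risk and n1
  at risk in group 1, the expected group-1 events are d*n1/n with
  hypergeometric variance d*(n1/n)*(1 - n1/n)*(n - d)/(n - 1); the
  statistic (sum O - sum E)^2 / sum V is chi-square with 1 df under the
  null.  A permutation p-value is available for small cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["median_split", "km_estimator", "logrank_test", "KMCurve",
           "read_survival_table"]


def median_split(markers) -> np.ndarray:
    """Label each subject 'high' (marker > median) or 'low' (<= median)."""
    markers = np.asarray(markers, dtype=float)
    if markers.size < 2:
        raise DataError("median split needs at least two subjects")
    med = float(np.median(markers))
    labels = np.where(markers > med, "high", "low")
    if (labels == "low").all():
        warnings.warn("all markers identical or below median: "
                      "every subject labelled 'low'")
    return labels


@dataclass
class KMCurve:
    """Kaplan-Meier curve over the distinct event times."""

    event_times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): the step function evaluated at time t (S(0) = 1)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "n_risk": self.n_risk,
            "n_event": self.n_event, "survival": self.survival,
        })


def km_estimator(times, events) -> KMCurve:
    """Product-limit survival estimate from right-censored data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("empty survival table")
    if np.any(times <= 0):
        raise DataError("times must be positive")
    event_times = np.unique(times[events == 1])
    n_risk = np.empty(event_times.size, dtype=int)
    n_event = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size, dtype=float)
    s = 1.0
    for i, t in enumerate(event_times):
        n_risk[i] = int(np.sum(times >= t))  # censored at t still at risk
        n_event[i] = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - n_event[i] / n_risk[i]
        surv[i] = s
    return KMCurve(event_times=event_times, n_risk=n_risk,
                   n_event=n_event, survival=surv)


def _logrank_statistic(times, events, mask1) -> float:
    event_times = np.unique(times[events == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & mask1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & mask1).sum())
        O += d1
        E += d * n1 / n
        if n > 1:  # single-subject stratum contributes no variance
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O - E) ** 2 / V


def logrank_test(times, events, groups, method: str = "chisq",
                 n_permutations: int = 2000,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (statistic, p_value).

    ``method`` is "chisq" (1-df chi-square reference, standard practice)
    or "permutation" (group labels permuted ``n_permutations`` times, for
    small cohorts where the chi-square approximation is shaky).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise DataError(f"log-rank needs exactly 2 groups, got {labels.size}")
    mask1 = groups == labels[0]
    if mask1.all() or not mask1.any():
        raise DataError("one group is empty")

    stat = _logrank_statistic(times, events, mask1)
    if method == "chisq":
        p = float(chi2.sf(stat, df=1))
    elif method == "permutation":
        rng = rng or np.random.default_rng()
        n1 = int(mask1.sum())
        hits = 0
        for _ in range(n_permutations):
            perm = np.zeros(times.size, dtype=bool)
            perm[rng.choice(times.size, size=n1, replace=False)] = True
            if _logrank_statistic(times, events, perm) >= stat:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise DataError(f"unknown method {method!r}")
    return float(stat), p


def read_survival_table(path) -> pd.DataFrame:
    """Read a survival TSV (subject, time, event, marker)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    required = {"subject", "time", "event", "marker"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    if df[["time", "event", "marker"]].isna().any().any():
        raise DataError(f"{path}: missing values in survival table")
    if (df["time"] <= 0).any():
        raise DataError(f"{path}: times must be positive")
    return df
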