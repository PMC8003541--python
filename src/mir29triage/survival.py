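"""Kaplan-Meier estimation, the Gehan-Breslow-Wilcoxon test, and
score-based high/low patient stratification.

The two-group comparison is a weighted log-rank test with weight
w_j = n_j (the total number at risk) at each distinct event time — the
Gehan-Breslow-Wilcoxon generalization, which emphasizes early differences:

    U    = sum_j w_j (d_1j - e_1j)
    Var  = sum_j w_j^2 v_j
    chi2 = U^2 / Var,   p from chi-square with 1 df,

with e_1j = d_j n_1j / n_j the hypergeometric expectation and
v_j = d_j (n_1j/n_j) (1 - n_1j/n_j) (n_j - d_j) / (n_j - 1) the tie-corrected
hypergeometric variance.  Setting w_j = 1 recovers the plain log-rank test
(available via ``weighting="logrank"``).

At tied times, events are handled before censorings (the standard product-
limit convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimate",
    "gbw_test",
    "stratify_by_score",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    event_times: np.ndarray  # ascending, distinct, events only
    at_risk: np.ndarray      # n_j just before each event time
    events: np.ndarray       # d_j at each event time
    survival: np.ndarray     # S(t_j) = prod_{i<=j} (1 - d_i/n_i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def _check_samples(samples: pd.DataFrame) -> pd.DataFrame:
    if len(samples) == 0:
        raise ValueError("empty survival table")
    if (samples["time"] <= 0).any():
        raise ValueError("nonpositive survival time")
    return samples


def km_estimate(samples: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate from (time, event) records.

    ``samples`` needs columns ``time`` (positive) and ``event`` (1 = event,
    0 = censored).  Censorings tied with an event time are counted as still
    at risk at that time.
    """
    _check_samples(samples)
    time = samples["time"].to_numpy(dtype=float)
    event = samples["event"].to_numpy(dtype=int)
    n = len(time)
    event_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in event_times])
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    surv = np.cumprod(1.0 - d / at_risk) if len(event_times) else np.array([])
    return KMCurve(
        event_times=event_times,
        at_risk=at_risk.astype(int) if len(event_times) else np.array([], dtype=int),
        events=d.astype(int) if len(event_times) else np.array([], dtype=int),
        survival=surv,
    )


def gbw_test(
    samples: pd.DataFrame, weighting: str = "gehan-breslow-wilcoxon"
) -> tuple[float, float]:
    """Two-group weighted log-rank comparison; returns (chi2, p-value).

    Default weighting is Gehan-Breslow-Wilcoxon (w_j = number at risk);
    ``weighting="logrank"`` gives the unweighted test.  Requires exactly two
    non-empty groups; returns (NaN, NaN) with a warning if no events
    occurred at all.
    """
    _check_samples(samples)
    groups = pd.unique(samples["group"])
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    for g in groups:
        if (samples["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    if (samples["event"] == 0).all():
        warnings.warn("no events observed; test undefined")
        return float("nan"), float("nan")

    time = samples["time"].to_numpy(dtype=float)
    event = samples["event"].to_numpy(dtype=int)
    in_g1 = (samples["group"] == groups[0]).to_numpy()

    event_times = np.unique(time[event == 1])
    u = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = at_risk.sum()
        n_1j = (at_risk & in_g1).sum()
        dying = (time == t) & (event == 1)
        d_j = dying.sum()
        d_1j = (dying & in_g1).sum()
        w = float(n_j) if weighting.startswith("gehan") else 1.0
        e_1j = d_j * n_1j / n_j
        if n_j > 1:
            v_j = (
                d_j * (n_1j / n_j) * (1.0 - n_1j / n_j) * (n_j - d_j) / (n_j - 1.0)
            )
        else:
            v_j = 0.0
        u += w * (d_1j - e_1j)
        var += w * w * v_j
    if var == 0:
        return 0.0, 1.0
    chi2 = u * u / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratify_by_score(
    expr: pd.DataFrame, gene_set: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Split subjects into high/low by the mean z-score of a gene set.

    ``expr`` is subjects (rows) x genes (columns).  Each gene in
    ``gene_set`` is z-scored across subjects, scores are the per-subject
    mean, and the split is at the median with ties (including subjects
    exactly at the median) assigned "low".  Returns (group labels, scores).
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in expr.columns]
    if missing:
        raise ValueError(f"genes absent from expression table: {missing}")
    if len(expr) < 2:
        raise ValueError("need at least 2 subjects")
    sub = expr[list(gene_set)].astype(float)
    sd = sub.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.any():
        warnings.warn("all genes constant across subjects; all subjects -> low")
        scores = pd.Series(0.0, index=expr.index, name="score")
        return pd.Series("low", index=expr.index, name="group"), scores
    z = (sub.loc[:, usable] - sub.loc[:, usable].mean(axis=0)) / sd[usable]
    scores = z.mean(axis=1).rename("score")
    med = scores.median()
    group = pd.Series(
        np.where(scores > med, "high", "low"), index=expr.index, name="group"
    )
    if (group == "low").all():
        warnings.warn("degenerate split: all subjects at or below the median")
    return group, scores
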