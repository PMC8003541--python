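"""Bench-assay quantification: ddCt qPCR, dual-luciferase normalization,
and the standard two-group / multi-group location tests.

Relative qPCR quantification follows the comparative-Ct convention with
amplification efficiency fixed at 2 (perfect doubling per cycle):

    dCt   = Ct_target - Ct_reference          (per sample, replicates
                                               averaged first)
    ddCt  = mean dCt_condition - mean dCt_calibrator
    RQ    = 2 ** -ddCt

Reference-gene subtraction makes RQ invariant to any constant Ct shift.
Dual-luciferase readings are normalized per sample as experimental /
control signal; condition means are then expressed relative to a baseline
condition, and the seed-mutant rescue index is the mutant-reporter fold
change under mimic minus the wildtype-reporter fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct_quantify",
    "luciferase_normalize",
    "rescue_index",
    "group_compare",
]


def ddct_quantify(
    records: pd.DataFrame, calibrator_condition: str, base: float = 2.0
) -> pd.DataFrame:
    """Relative quantity per condition by the comparative-Ct method.

    ``records`` needs columns sample_id, condition, role ("target" /
    "reference") and ct; technical replicates of a sample are averaged
    before dCt is formed.  Samples with no reference measurement are
    dropped with a warning.  Returns a DataFrame indexed by condition with
    columns rq, ddct, sem (SEM of RQ propagated from the per-sample dCt
    spread) and n.
    """
    if calibrator_condition not in set(records["condition"]):
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    per_sample = (
        records.groupby(["sample_id", "condition", "role"])["ct"]
        .mean()
        .unstack("role")
        .reset_index()
    )
    missing_ref = per_sample["reference"].isna() | per_sample["target"].isna()
    if missing_ref.any():
        warnings.warn(
            f"dropping {int(missing_ref.sum())} sample(s) without a reference Ct"
        )
        per_sample = per_sample.loc[~missing_ref]
    n_reps = per_sample.groupby("condition").size()
    if (n_reps < 2).any():
        warnings.warn("fewer than 2 replicates in some condition")
    per_sample["dct"] = per_sample["target"] - per_sample["reference"]

    grp = per_sample.groupby("condition")["dct"]
    mean_dct = grp.mean()
    sem_dct = grp.sem().fillna(0.0)
    ddct = mean_dct - mean_dct[calibrator_condition]
    rq = base ** (-ddct)
    # delta-method SEM of RQ from the dCt SEM
    sem_rq = rq * np.log(base) * sem_dct
    return pd.DataFrame(
        {"rq": rq, "ddct": ddct, "sem": sem_rq, "n": grp.size()}
    )


def luciferase_normalize(
    records: pd.DataFrame, baseline_condition: str, flip_channels: bool = False
) -> pd.DataFrame:
    """Normalized dual-luciferase activity per condition.

    Each sample's ratio is experimental_signal / control_signal (the
    UTR-bearing reporter over the co-expressed normalizer; ``flip_channels``
    inverts the orientation for the opposite vector layout).  Condition
    mean ratios are divided by the baseline condition's mean ratio.
    Returns a DataFrame indexed by condition with columns activity, sem, n.
    """
    if (records["control_signal"] <= 0).any():
        raise ValueError("control signal must be positive")
    if baseline_condition not in set(records["condition"]):
        raise ValueError(f"baseline condition {baseline_condition!r} absent")
    r = records.copy()
    if flip_channels:
        if (r["experimental_signal"] <= 0).any():
            raise ValueError("experimental signal must be positive to flip channels")
        r["ratio"] = r["control_signal"] / r["experimental_signal"]
    else:
        r["ratio"] = r["experimental_signal"] / r["control_signal"]
    grp = r.groupby("condition")["ratio"]
    base = grp.mean()[baseline_condition]
    return pd.DataFrame(
        {"activity": grp.mean() / base, "sem": grp.sem().fillna(0.0) / base,
         "n": grp.size()}
    )


def rescue_index(
    records: pd.DataFrame,
    wt_mimic: str = "wt_mimic",
    wt_baseline: str = "wt_control",
    mut_mimic: str = "mut_mimic",
    mut_baseline: str = "mut_control",
) -> float:
    """Seed-mutant rescue index from a four-condition luciferase experiment.

    (mutant-reporter fold change under mimic) - (wildtype-reporter fold
    change under mimic); positive when mutating the binding site rescues
    the mimic-induced repression, zero when the mimic has no effect on
    either reporter.
    """
    means = (
        records.assign(ratio=records["experimental_signal"] / records["control_signal"])
        .groupby("condition")["ratio"]
        .mean()
    )
    for cond in (wt_mimic, wt_baseline, mut_mimic, mut_baseline):
        if cond not in means.index:
            raise ValueError(f"condition {cond!r} absent from records")
    wt_fold = means[wt_mimic] / means[wt_baseline]
    mut_fold = means[mut_mimic] / means[mut_baseline]
    return float(mut_fold - wt_fold)


def group_compare(groups: list, mode: str = "ttest") -> tuple[float, float]:
    """Unpaired two-tailed t-test (pooled variance) or one-way ANOVA.

    ``groups`` is a list of per-group value sequences.  Returns (statistic,
    p-value); (NaN, NaN) with a warning when every group has zero within-
    group variance (the reference distributions degenerate).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if all(a.var(ddof=1) == 0 for a in arrays):
        warnings.warn("zero within-group variance in all groups; test undefined")
        return float("nan"), float("nan")
    if mode == "ttest":
        if len(arrays) != 2:
            raise ValueError("ttest requires exactly 2 groups")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if mode == "anova":
        if len(arrays) < 2:
            raise ValueError("anova requires >= 2 groups")
        res = stats.f_oneway(*arrays)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")
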