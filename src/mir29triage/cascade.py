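"""The four-criterion evidence cascade for miR-29 target candidates.

A gene becomes a candidate target only if it satisfies all four filters:

1. mimic_down — repressed by miR-29a mimic transfection:
   log2FC < -0.5 and FDR < 0.05 (both strict);
2. cohort_up — upregulated in primary melanoma vs nevus:
   log2FC >= 0.3 and FDR <= 0.05 (both non-strict);
3. sites — high-confidence conserved binding-site consensus:
   supported by >= 8 prediction algorithms and flagged conserved;
4. anticorr — expression anti-correlated with pri-miR-29b2~c:
   Pearson r <= -0.3 (non-strict).

The strict/non-strict boundary semantics are deliberate and encoded in
``CascadeThresholds``; a record sitting exactly at -0.5 mimic log2FC fails
stage 1 while one at exactly 0.3 cohort log2FC passes stage 2.  Every input
gene is retained in a per-stage boolean ledger so near-misses stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CascadeThresholds",
    "CandidateTable",
    "correlate",
    "anticorrelation_profile",
    "run_cascade",
]


@dataclass(frozen=True)
class CascadeThresholds:
    """Stage cut-offs; defaults are the published selection values."""

    mimic_lfc_max: float = -0.5   # strict <
    mimic_fdr_max: float = 0.05   # strict <
    cohort_lfc_min: float = 0.3   # non-strict >=
    cohort_fdr_max: float = 0.05  # non-strict <=
    min_algorithms: int = 8       # non-strict >=
    corr_max: float = -0.3        # non-strict <=
    corr_method: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if self.mimic_lfc_max >= 0:
            raise ValueError("mimic_lfc_max must be negative")
        if self.cohort_lfc_min <= 0:
            raise ValueError("cohort_lfc_min must be positive")
        if self.corr_max >= 0:
            raise ValueError("corr_max must be negative")
        if self.min_algorithms < 1:
            raise ValueError("min_algorithms must be >= 1")


@dataclass
class CandidateTable:
    """Cascade output: the surviving candidates plus the full gene ledger."""

    candidates: pd.DataFrame
    ledger: pd.DataFrame


def correlate(expr, mir_vector, method: str = "pearson") -> float:
    """Correlation between one gene's per-sample values and the pri-miR vector.

    Pearson product-moment by default (Spearman available); callers are
    expected to pass log2(normalized + 1) expression values.  Returns NaN if
    either vector is constant.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(mir_vector, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def anticorrelation_profile(
    counts: pd.DataFrame,
    factors: pd.Series,
    mir_expression: pd.Series,
    method: str = "pearson",
) -> pd.Series:
    """Per-gene correlation with pri-miR-29b2~c on log2(normalized + 1) reads.

    Both the gene counts and the pri-miR counts are depth-normalized by the
    sample size factors before the log transform.
    """
    s = factors.reindex(counts.columns).to_numpy()
    gene_log = np.log2(counts.to_numpy(dtype=float) / s[None, :] + 1.0)
    mir_log = np.log2(mir_expression.reindex(counts.columns).to_numpy() / s + 1.0)
    r = pd.Series(
        [correlate(row, mir_log, method=method) for row in gene_log],
        index=counts.index,
        name="r",
    )
    return r


def run_cascade(
    mimic_de: pd.DataFrame,
    cohort_de: pd.DataFrame,
    summaries: pd.DataFrame,
    correlations: pd.Series,
    thresholds: CascadeThresholds = CascadeThresholds(),
) -> CandidateTable:
    """Intersect the four evidence streams into a ranked candidate table.

    The gene universe is the union of all streams; a gene missing from a
    stream (or carrying NaN evidence there) fails that stage but stays in
    the ledger.  Candidates are sorted by r ascending, then mimic log2FC
    ascending, then gene_id.  Duplicate gene ids within a stream are
    rejected.
    """
    t = thresholds

    def _indexed(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if df.index.name != "gene_id" and "gene_id" in df.columns:
            df = df.set_index("gene_id")
        if df.index.duplicated().any():
            raise ValueError(f"duplicate gene_ids in {name} stream")
        return df

    mimic = _indexed(mimic_de, "mimic DE")
    cohort = _indexed(cohort_de, "cohort DE")
    summ = _indexed(summaries, "site summary")
    if correlations.index.duplicated().any():
        raise ValueError("duplicate gene_ids in correlation stream")

    universe = (
        mimic.index.union(cohort.index).union(summ.index).union(correlations.index)
    )
    led = pd.DataFrame(index=universe.rename("gene_id"))
    led["mimic_lfc"] = mimic["log2fc"].reindex(universe)
    led["mimic_fdr"] = mimic["fdr"].reindex(universe)
    led["cohort_lfc"] = cohort["log2fc"].reindex(universe)
    led["cohort_fdr"] = cohort["fdr"].reindex(universe)
    led["n_algorithms"] = summ["n_algorithms"].reindex(universe)
    led["conserved"] = (
        summ["conserved"].reindex(universe).astype("boolean").fillna(False).astype(bool)
    )
    led["r"] = correlations.reindex(universe)

    # NaN comparisons are False, so missing evidence fails the stage.
    led["pass_mimic_down"] = (
        (led["mimic_lfc"] < t.mimic_lfc_max) & (led["mimic_fdr"] < t.mimic_fdr_max)
    )
    led["pass_cohort_up"] = (
        (led["cohort_lfc"] >= t.cohort_lfc_min) & (led["cohort_fdr"] <= t.cohort_fdr_max)
    )
    led["pass_sites"] = (led["n_algorithms"] >= t.min_algorithms) & led["conserved"]
    led["pass_anticorr"] = led["r"] <= t.corr_max
    led["candidate"] = (
        led["pass_mimic_down"]
        & led["pass_cohort_up"]
        & led["pass_sites"]
        & led["pass_anticorr"]
    )

    cands = (
        led.loc[led["candidate"]]
        .reset_index()
        .sort_values(
            ["r", "mimic_lfc", "gene_id"], ascending=[True, True, True],
            kind="stable",
        )
        .reset_index(drop=True)
    )
    return CandidateTable(candidates=cands, ledger=led.reset_index())
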