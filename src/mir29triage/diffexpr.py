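"""Negative-binomial differential expression with BH-FDR, from first principles.

Implements the minimal bulk RNA-seq DE stack needed by the two contrasts of
the target-triage pipeline (miR-29a mimic vs control transfection; primary
melanoma vs nevus cohort):

* median-of-ratios size factors (geometric-mean reference, factors rescaled
  to geometric mean 1), with an upper-quartile fallback when no gene is
  observed in every sample;
* per-gene method-of-moments dispersion on normalized counts, averaged
  across the two condition groups and shrunk 50/50 toward a running-median
  trend over the 50 nearest genes by mean expression;
* a Wald test on the pseudocounted log2 fold change with a delta-method
  standard error under Var(K) = mu + phi * mu^2;
* Benjamini-Hochberg step-up FDR, applied within each contrast.

No external DE package is called; the stack is deliberately small, fully
deterministic, and vectorized over genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "size_factors",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "run_de",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts with a two-level condition.

    ``counts`` is genes (rows, indexed by gene_id) x samples (columns);
    ``condition`` maps sample_id -> level.  ``mir_expression`` optionally
    carries a per-sample pri-miR-29b2~c read count emitted alongside cohort
    simulations.
    """

    counts: pd.DataFrame
    condition: pd.Series
    mir_expression: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene_ids")
        if not self.counts.columns.equals(self.condition.index):
            self.condition = self.condition.reindex(self.counts.columns)
            if self.condition.isna().any():
                raise ValueError("condition labels missing for some samples")
        levels, n_per = np.unique(self.condition.to_numpy(), return_counts=True)
        if len(levels) == 2 and (n_per < 2).any():
            small = levels[n_per < 2][0]
            raise ValueError(f"condition level {small!r} has <2 samples")

    @property
    def levels(self) -> list[str]:
        return sorted(pd.unique(self.condition))


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean rescaled to 1.

    The per-gene reference is the geometric mean across samples over genes
    with no zero count; each sample's factor is the median of its ratios to
    the reference.  If no gene is nonzero in every sample, falls back to
    upper-quartile (75th percentile of nonzero counts) normalization with a
    logged warning.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if all_nonzero.any():
        ref = np.exp(np.log(counts[all_nonzero]).mean(axis=1))
        factors = np.median(counts[all_nonzero] / ref[:, None], axis=0)
    else:
        logger.warning(
            "no gene observed in all samples; falling back to upper-quartile "
            "normalization"
        )
        warnings.warn("median-of-ratios unavailable; using upper-quartile factors")
        factors = np.array(
            [
                np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0
                for col in counts.T
            ]
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def estimate_dispersion(cm: CountMatrix, factors: pd.Series) -> pd.Series:
    """Per-gene NB dispersion phi with Var = mu + phi * mu^2.

    Method of moments within each condition on normalized counts,
    phi_g = max(0, (s^2 - mu) / mu^2), averaged across conditions, then
    shrunk 50/50 toward the median raw phi of the 50 nearest genes ranked by
    mean normalized count.  Genes with all-zero counts are returned as NaN
    and excluded from testing downstream.
    """
    norm = cm.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    cond = cm.condition.to_numpy()
    raws = []
    for level in np.unique(cond):
        sub = norm[:, cond == level]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), np.nan)
        raws.append(raw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN genes
        raw_phi = np.nanmean(np.vstack(raws), axis=0)
    all_zero = (cm.counts.to_numpy() == 0).all(axis=1)
    raw_phi[all_zero] = np.nan

    base_mean = norm.mean(axis=1)
    order = np.argsort(base_mean, kind="stable")
    phi_sorted = raw_phi[order]
    n = len(phi_sorted)
    trend_sorted = np.empty(n)
    half = 25  # 50-gene window
    for rank in range(n):
        lo, hi = max(0, rank - half), min(n, rank + half)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trend_sorted[rank] = np.nanmedian(phi_sorted[lo:hi])
    trend = np.empty(n)
    trend[order] = trend_sorted

    phi = 0.5 * raw_phi + 0.5 * np.where(np.isnan(trend), raw_phi, trend)
    return pd.Series(phi, index=cm.counts.index, name="dispersion")


def wald_test(
    cm: CountMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    *,
    pseudocount: float = 0.5,
    min_count_filter: float = 5.0,
    level_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene Wald test of the log2 fold change between two conditions.

    log2fc = log2((m2 + c) / (m1 + c)) on group means of normalized counts
    (level2 relative to level1; default level order is sorted label order).
    The SE comes from the delta method with per-observation NB variance
    mu + phi * mu^2 evaluated at mu_gs = m_group * s_s.  Genes whose mean
    normalized count across all samples is below ``min_count_filter`` are
    excluded from testing (NaN p-value and FDR); BH is applied to the tested
    genes only.

    Returns a DataFrame indexed by gene_id with columns base_mean, log2fc,
    se, pvalue, fdr.
    """
    cond = cm.condition.to_numpy()
    levels = list(level_order) if level_order is not None else cm.levels
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    for level in levels:
        if not (cond == level).any():
            raise ValueError(f"condition level {level!r} has no samples")

    norm = cm.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    phi = dispersions.reindex(cm.counts.index).to_numpy()
    base_mean = norm.mean(axis=1)

    means, variances = [], []
    s = factors.to_numpy()
    for level in levels:
        mask = cond == level
        m = norm[:, mask].mean(axis=1)
        # Var(mean of K_gs / s_s) = (1/n^2) * sum_s (mu_gs + phi mu_gs^2) / s_s^2
        mu_gs = m[:, None] * s[None, mask]
        phi_safe = np.nan_to_num(phi, nan=0.0)
        var_obs = (mu_gs + phi_safe[:, None] * mu_gs**2) / s[None, mask] ** 2
        means.append(m)
        variances.append(var_obs.sum(axis=1) / mask.sum() ** 2)
    m1, m2 = means
    v1, v2 = variances

    c = pseudocount
    log2fc = np.log2(m2 + c) - np.log2(m1 + c)
    ln2 = np.log(2.0)
    se = np.sqrt(v1 / (m1 + c) ** 2 + v2 / (m2 + c) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    tested = (base_mean >= min_count_filter) & ~np.isnan(phi)
    pvalue = np.where(tested, pvalue, np.nan)
    fdr = bh_adjust(pvalue)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "fdr": fdr,
        },
        index=cm.counts.index.rename("gene_id"),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m/j) p_(j), capped at 1 and mapped back to input
    order; NaN entries are propagated and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def run_de(cm: CountMatrix, **wald_kwargs) -> pd.DataFrame:
    """Size factors -> dispersion -> Wald test -> BH, in one call."""
    factors = size_factors(cm)
    phi = estimate_dispersion(cm, factors)
    return wald_test(cm, factors, phi, **wald_kwargs)
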