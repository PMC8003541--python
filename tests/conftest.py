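import numpy as np
import pandas as pd
import pytest

from mir29triage import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A desk-sized study: fast enough for per-test simulation."""
    return SimConfig(n_genes=300, n_targets=5, seed=11)


@pytest.fixture
def default_config() -> SimConfig:
    """The full default study design (2000 genes, 9 targets, 3v3, 23v57)."""
    return SimConfig(seed=7)


def brute_force_sites(utr: str, seed: str) -> set[tuple[int, str]]:
    """Naive all-offset enumeration of the four literal site patterns.

    Independent of the scanner: builds the four literal strings from the
    seed by direct base-by-base complementation and tests each with slicing
    at every offset, keeping the maximal type per seed-core position.
    """
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    rc = lambda s: "".join(comp[c] for c in reversed(s))
    core6 = rc(seed[:6])
    m8 = rc(seed[6])
    u = utr.upper().replace("T", "U")
    out: set[tuple[int, str]] = set()
    for j in range(len(u) - 5):
        if u[j : j + 6] != core6:
            continue
        if j >= 1 and u[j - 1 : j + 7] == m8 + core6 + "A":
            out.add((j - 1, "8mer"))
        elif j >= 1 and u[j - 1 : j + 6] == m8 + core6:
            out.add((j - 1, "7mer-m8"))
        elif u[j : j + 7] == core6 + "A":
            out.add((j, "7mer-A1"))
        else:
            out.add((j, "6mer"))
    return out


def gbw_permutation_pvalue(
    tab: pd.DataFrame, n_draws: int, seed: int = 0
) -> float:
    """Monte-Carlo permutation p-value of the Gehan-Breslow-Wilcoxon chi2.

    Recomputes the weighted-logrank statistic directly from its formula
    (vectorized across label permutations), independent of the package's
    implementation, and returns the fraction of permuted statistics at
    least as large as the observed one.
    """
    rng = np.random.default_rng(seed)
    time = tab["time"].to_numpy(dtype=float)
    event = tab["event"].to_numpy(dtype=int)
    groups = pd.unique(tab["group"])
    in_g1 = (tab["group"] == groups[0]).to_numpy()
    event_times = np.unique(time[event == 1])
    at_risk = time[:, None] >= event_times[None, :]          # n x J
    dying = (time[:, None] == event_times[None, :]) & (event[:, None] == 1)
    n_j = at_risk.sum(axis=0).astype(float)
    d_j = dying.sum(axis=0).astype(float)

    def chi2_for(masks: np.ndarray) -> np.ndarray:          # P x n boolean
        n_1j = masks.astype(float) @ at_risk                 # P x J
        d_1j = masks.astype(float) @ dying
        e_1j = d_j * n_1j / n_j
        frac = n_1j / n_j
        with np.errstate(invalid="ignore", divide="ignore"):
            v_j = np.where(
                n_j > 1, d_j * frac * (1 - frac) * (n_j - d_j) / (n_j - 1), 0.0
            )
        w = n_j
        u = (w * (d_1j - e_1j)).sum(axis=1)
        var = (w**2 * v_j).sum(axis=1)
        return np.where(var > 0, u**2 / var, 0.0)

    obs = chi2_for(in_g1[None, :])[0]
    perms = np.array([rng.permutation(in_g1) for _ in range(n_draws)])
    return float((chi2_for(perms) >= obs - 1e-12).mean())
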