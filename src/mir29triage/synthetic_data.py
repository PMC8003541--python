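"""Synthetic study generator with known ground truth.

Emulates the four data resources the target-triage pipeline integrates,
each with planted, recoverable truth:

1. a 3-vs-3 miRNA-mimic transfection RNA-seq experiment with planted
   repressed target genes (negative-binomial counts);
2. a 23-nevus / 57-melanoma cohort with planted target upregulation and a
   latent per-sample pri-miR-29b2~c factor that induces target
   anti-correlation;
3. 3'UTR FASTA sequences with planted seed-match sites at recorded
   coordinates plus an external-predictor vote table;
4. survival times exponentially coupled to a per-subject score, with
   independent uniform censoring; plus qPCR Ct tables and dual-luciferase
   readings with planted fold changes.

Counts follow NB(mean mu_gs = s_s * q_g * 2^(x_s * beta_g), variance
mu + phi * mu^2) with per-sample depth factors s_s log-uniform in [0.5, 2].
All randomness for a call flows from the config seed through one
numpy Generator; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .seedscan import (
    MIR29A,
    MatureMiRNA,
    _seed_patterns,
    find_seed_sites,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_counts",
    "generate_utrs_and_votes",
    "generate_survival",
    "generate_ct_table",
    "generate_luciferase_table",
    "write_study",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the study design the pipeline addresses: a 3v3 mimic
    transfection with 9 planted targets repressed by one log2 unit, and a
    23-nevus / 57-melanoma cohort with +0.6 log2 target upregulation and a
    latent pri-miR-29b2~c factor of strength 0.5.
    """

    n_genes: int = 2000
    n_targets: int = 9
    mimic_effect_log2: float = -1.0
    cohort_effect_log2: float = 0.6
    n_mimic: int = 3
    n_control: int = 3
    n_nevus: int = 23
    n_melanoma: int = 57
    dispersion: float = 0.1
    anticorr_beta: float = 0.5
    vote_high: int = 10
    vote_low: int = 2
    hazard_log_hr: float = 0.8
    seed: int = 7
    # secondary knobs
    n_algorithms_total: int = 12
    baseline_hazard: float = 1.0
    utr_len_range: tuple[int, int] = (200, 2000)
    ct_noise_sd: float = 0.05
    n_ct_replicates: int = 3
    allow_decoys: bool = False

    def __post_init__(self) -> None:
        for name in (
            "mimic_effect_log2", "cohort_effect_log2", "dispersion",
            "anticorr_beta", "hazard_log_hr", "baseline_hazard",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_targets >= self.n_genes:
            raise ValueError("n_targets must be < n_genes")
        if min(self.n_mimic, self.n_control, self.n_nevus, self.n_melanoma) < 2:
            raise ValueError("every arm needs >=2 samples")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0 <= self.vote_low <= self.n_algorithms_total
                and 0 <= self.vote_high <= self.n_algorithms_total):
            raise ValueError("vote means must lie in [0, n_algorithms_total]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """One generator per logical stream, all derived from the config seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Planted truth for one study: who the targets are and what was planted."""

    target_ids: list[str] = field(default_factory=list)
    mimic_log2fc: dict[str, float] = field(default_factory=dict)
    cohort_log2fc: dict[str, float] = field(default_factory=dict)
    sites: dict[str, list[dict]] = field(default_factory=dict)
    votes: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_counts(
    config: SimConfig, contrast: str
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate NB counts for the ``mimic`` or ``cohort`` contrast.

    Targets (the first n_targets gene ids, recorded in the returned
    GroundTruth) carry the planted log2 fold change; all other genes are
    null.  In the cohort contrast a latent standard-normal per-sample factor
    m_s — standing for pri-miR-29b2~c normalized expression — multiplies
    target means by 2^(-anticorr_beta * m_s), and a matching per-sample
    pri-miR read count is emitted on ``CountMatrix.mir_expression``.
    """
    if contrast not in ("mimic", "cohort"):
        raise ValueError(f"unknown contrast {contrast!r}")
    rng = config.rng(stream=0 if contrast == "mimic" else 1)

    genes = _gene_ids(config.n_genes)
    targets = genes[: config.n_targets]
    if contrast == "mimic":
        n1, n2 = config.n_control, config.n_mimic
        labels = ["control"] * n1 + ["mimic"] * n2
        effect = config.mimic_effect_log2
    else:
        n1, n2 = config.n_nevus, config.n_melanoma
        labels = ["nevus"] * n1 + ["melanoma"] * n2
        effect = config.cohort_effect_log2
    n_samples = n1 + n2
    x = np.array([0] * n1 + [1] * n2, dtype=float)

    beta = np.zeros(config.n_genes)
    beta[: config.n_targets] = effect
    q = np.exp(rng.normal(np.log(200.0), 1.2, size=config.n_genes))
    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))

    mu = s[None, :] * q[:, None] * 2.0 ** (x[None, :] * beta[:, None])
    mir = None
    if contrast == "cohort":
        m_s = rng.normal(0.0, 1.0, size=n_samples)
        mu[: config.n_targets, :] *= 2.0 ** (-config.anticorr_beta * m_s[None, :])
        mir_mu = 500.0 * s * 2.0**m_s
        r_mir = 1.0 / config.dispersion
        mir_counts = rng.negative_binomial(r_mir, r_mir / (r_mir + mir_mu))
        mir = pd.Series(
            mir_counts,
            index=[f"{lab}{i}" for i, lab in enumerate(labels)],
            name="pri-miR-29b2~c",
        )

    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    sample_ids = [f"{lab}{i}" for i, lab in enumerate(labels)]
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                            columns=sample_ids),
        condition=pd.Series(labels, index=sample_ids, name="condition"),
        mir_expression=mir,
    )
    truth = GroundTruth(
        target_ids=list(targets),
        mimic_log2fc={
            g: (config.mimic_effect_log2 if g in targets else 0.0) for g in genes
        },
        cohort_log2fc={
            g: (config.cohort_effect_log2 if g in targets else 0.0) for g in genes
        },
    )
    return cm, truth


def _scrub_accidental_sites(
    seq: np.ndarray, core6: str, bases: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rewrite accidental 6-nt seed cores until none remain (DNA alphabet)."""
    pattern = re.compile(f"(?={core6.replace('U', 'T')})")
    k = 6
    while True:
        hits = [m.start() for m in pattern.finditer(seq.tobytes().decode())]
        if not hits:
            return seq
        for i in hits:
            seq[i : i + k] = rng.choice(bases, size=k)


def generate_utrs_and_votes(
    config: SimConfig,
    truth: GroundTruth,
    mirna: MatureMiRNA = MIR29A,
) -> tuple[str, pd.DataFrame]:
    """Emit 3'UTR FASTA text with planted sites plus a predictor-vote table.

    Background UTRs (uniform base composition, lengths uniform in
    ``utr_len_range``) are rejection-scrubbed of accidental seed cores so
    the planted coordinates are the complete truth, unless ``allow_decoys``
    re-enables accidental matches.  Each target gets one planted 8mer site;
    coordinates and types are recorded on ``truth.sites``.  Votes are
    Binomial(n_algorithms_total, vote_mean / n_algorithms_total); targets
    are flagged conserved, non-targets conserved with probability 1/2.
    """
    rng = config.rng(stream=2)
    genes = _gene_ids(config.n_genes)
    targets = set(truth.target_ids)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    pats = _seed_patterns(mirna)
    site_dna = pats["8mer"].replace("U", "T")

    lo, hi = config.utr_len_range
    if len(site_dna) > lo:
        raise ValueError("planted site longer than the shortest allowed UTR")
    records = []
    truth.sites = {}
    for g in genes:
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(bases, size=length)
        if not config.allow_decoys:
            seq = _scrub_accidental_sites(seq, pats["6mer"], bases, rng)
        if g in targets:
            start = int(rng.integers(1, length - len(site_dna)))
            seq[start : start + len(site_dna)] = np.frombuffer(
                site_dna.encode(), dtype="S1"
            )
            # planting may abut random bases that recreate a core upstream;
            # verify the scan sees exactly the planted site, else re-scrub edges
            utr = seq.tobytes().decode()
            found = find_seed_sites(mirna, utr, gene_id=g)
            if not config.allow_decoys:
                while len(found) != 1:
                    extra = [st for st in found if st.start != start]
                    for st in extra:
                        seq[st.start : st.start + 6] = rng.choice(bases, size=6)
                    seq[start : start + len(site_dna)] = np.frombuffer(
                        site_dna.encode(), dtype="S1"
                    )
                    found = find_seed_sites(mirna, seq.tobytes().decode(), gene_id=g)
            truth.sites[g] = [
                {"start": start, "end": start + len(site_dna), "site_type": "8mer"}
            ]
        else:
            truth.sites[g] = []
        records.append((g, seq.tobytes().decode()))

    p_high = config.vote_high / config.n_algorithms_total
    p_low = config.vote_low / config.n_algorithms_total
    votes = {
        g: int(
            rng.binomial(
                config.n_algorithms_total, p_high if g in targets else p_low
            )
        )
        for g in genes
    }
    truth.votes = votes
    conserved = {
        g: 1 if g in targets else int(rng.random() < 0.5) for g in genes
    }

    fasta = "".join(f">{g}\n{seq}\n" for g, seq in records)
    support = pd.DataFrame(
        {
            "gene_id": genes,
            "n_algorithms": [votes[g] for g in genes],
            "conserved": [conserved[g] for g in genes],
        }
    )
    return fasta, support


def generate_survival(config: SimConfig, scores) -> pd.DataFrame:
    """Simulate a two-arm survival table coupled to a per-subject score.

    Event times are exponential with hazard h_i = h0 * exp(hazard_log_hr *
    z_i) on the standardized score; censoring is independent Uniform(0,
    3/h0), which keeps roughly 20-40% of subjects censored at defaults.
    Group is the median split of the score (ties -> low).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    rng = config.rng(stream=3)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    h0 = config.baseline_hazard
    hazard = h0 * np.exp(config.hazard_log_hr * z)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, 3.0 / h0, size=scores.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    group = np.where(scores > np.median(scores), "high", "low")
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(scores.size)],
            "time": time,
            "event": event,
            "group": group,
        }
    )


def generate_ct_table(config: SimConfig, fold_changes: dict[str, float]) -> pd.DataFrame:
    """Simulate a qPCR Ct table for planted per-gene fold changes.

    For each gene, treated wells shift the target Ct by -log2(F) relative to
    control while the reference gene (GAPDH stand-in) stays flat, so the
    standard relative quantification recovers RQ = F.  Gaussian well noise
    of sd ``ct_noise_sd`` is added to every reading.
    """
    rng = config.rng(stream=4)
    rows = []
    sd = config.ct_noise_sd
    for gene, fc in fold_changes.items():
        if not np.isfinite(fc) or fc <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
        base_ct = 24.0 + 4.0 * rng.random()
        ref_ct = 18.0 + 2.0 * rng.random()
        for condition, shift in (("control", 0.0), ("treated", -np.log2(fc))):
            for rep in range(config.n_ct_replicates):
                sample = f"{gene}_{condition}_r{rep}"
                rows.append(
                    {
                        "sample_id": sample, "gene_id": gene,
                        "reference_id": "GAPDH", "condition": condition,
                        "replicate": rep, "role": "target",
                        "ct": base_ct + shift + rng.normal(0.0, sd),
                    }
                )
                rows.append(
                    {
                        "sample_id": sample, "gene_id": gene,
                        "reference_id": "GAPDH", "condition": condition,
                        "replicate": rep, "role": "reference",
                        "ct": ref_ct + rng.normal(0.0, sd),
                    }
                )
    return pd.DataFrame(rows)


def generate_luciferase_table(
    config: SimConfig,
    repression: float = 0.6,
    rescue_fraction: float = 1.0,
    noise_sd: float = 0.02,
    n_replicates: int = 4,
) -> pd.DataFrame:
    """Simulate a dual-luciferase reporter experiment with seed-mutant rescue.

    Four conditions: wildtype / seed-mutant 3'UTR reporter, each with and
    without miRNA mimic.  The mimic multiplies the wildtype reporter ratio
    by ``repression``; mutating the seed site rescues a ``rescue_fraction``
    of that repression (1.0 = complete rescue).  Multiplicative lognormal
    noise of sd ``noise_sd`` on both channels.
    """
    rng = config.rng(stream=5)
    mut_effect = repression + rescue_fraction * (1.0 - repression)
    truth = {
        "wt_control": 1.0,
        "wt_mimic": repression,
        "mut_control": 1.0,
        "mut_mimic": mut_effect,
    }
    rows = []
    for condition, level in truth.items():
        for rep in range(n_replicates):
            control = 1000.0 * np.exp(rng.normal(0.0, noise_sd))
            experimental = 800.0 * level * np.exp(rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "sample_id": f"{condition}_r{rep}",
                    "condition": condition,
                    "experimental_signal": experimental,
                    "control_signal": control,
                }
            )
    return pd.DataFrame(rows)


def write_study(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input for one study to ``out_dir``.

    Emits counts + metadata TSVs for both contrasts, the pri-miR expression
    TSV, the UTR FASTA, the support TSV, and the ground-truth JSON.  Returns
    the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mimic_cm, truth = generate_counts(config, "mimic")
    cohort_cm, _ = generate_counts(config, "cohort")
    fasta, support = generate_utrs_and_votes(config, truth)

    for name, cm in (("mimic", mimic_cm), ("cohort", cohort_cm)):
        p = out / f"{name}_counts.tsv"
        cm.counts.to_csv(p, sep="\t")
        paths[f"{name}_counts"] = p
        p = out / f"{name}_metadata.tsv"
        cm.condition.rename_axis("sample_id").to_frame().to_csv(p, sep="\t")
        paths[f"{name}_metadata"] = p
    p = out / "mir_expression.tsv"
    cohort_cm.mir_expression.rename_axis("sample_id").to_frame().to_csv(p, sep="\t")
    paths["mir_expression"] = p

    paths["utrs"] = out / "utrs.fasta"
    paths["utrs"].write_text(fasta)
    paths["support"] = out / "support.tsv"
    support.to_csv(paths["support"], sep="\t", index=False)
    paths["truth"] = out / "ground_truth.json"
    paths["truth"].write_text(truth.to_json())
    return paths
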