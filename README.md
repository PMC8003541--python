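# mir29triage

Integrative prioritization of miR-29 target genes in melanoma, as a tested,
fully synthetic-data-driven pipeline.

The miR-29 microRNA family (miR-29a/b/c, from the miR-29b1~a and miR-29b2~c
genomic clusters) shares a single seed sequence and acts as a tumor
suppressor; its inactivation promotes melanoma. Finding the target mRNAs
that matter requires integrating several weak evidence streams. This
package implements that integration as a four-criterion cascade over a gene
universe:

1. **mimic_down** — downregulated after miR-29a mimic transfection:
   log₂FC < −0.5 and FDR < 0.05 (strict inequalities);
2. **cohort_up** — upregulated in primary melanoma vs benign nevus:
   log₂FC ≥ 0.3 and FDR ≤ 0.05;
3. **sites** — conserved seed-match consensus: predicted by ≥ 8 external
   algorithms and flagged conserved (an internal scanner classifies
   canonical 8mer / 7mer-m8 / 7mer-A1 / 6mer sites for the ledger);
4. **anticorr** — Pearson r ≤ −0.3 against per-sample pri-miR-29b2~c
   expression on log₂(normalized + 1) reads.

A gene is a candidate iff it passes all four; every gene keeps a per-stage
boolean ledger. Around the cascade the package provides, from first
principles: negative-binomial differential expression (median-of-ratios
size factors, method-of-moments dispersion with trend shrinkage, Wald test,
Benjamini–Hochberg FDR), Kaplan–Meier estimation with the
Gehan–Breslow–Wilcoxon weighted log-rank test (w_j = n_j at each event
time), mean-z-score high/low patient stratification, ΔΔCt qPCR
quantification (RQ = 2^−ΔΔCt), and dual-luciferase normalization with a
seed-mutant rescue index. A synthetic-data module generates every input
with planted ground truth (repressed targets, planted seed sites and
predictor votes, a latent pri-miR factor, score-coupled survival), so the
whole pipeline is testable end to end without any download.

## Worked example

Run the full seeded synthetic study — simulate, scan, test, intersect,
stratify — and report recovery of the planted targets:

```sh
mir29-triage demo --seed 11 --out-dir out --recall-floor 0
```

prints (among the run log):

```json
{
 "recall": 0.2222222222222222,
 "precision": 1.0,
 "recovered": ["G0002", "G0008"],
 "false_positives": []
}
```

With the default study design (2000 genes, 9 planted targets repressed by
one log₂ unit, a 3-vs-3 mimic experiment, a 23-nevus/57-melanoma cohort,
NB dispersion 0.1) the cascade admits essentially no false positives, and
recovery is limited by the statistical power of the 3-vs-3 mimic contrast:
with dispersion 0.1 a twofold change carries a Wald z of at most ≈ 2.7, so
only a minority of true targets clear FDR < 0.05 — the same behaviour an
established NB DE package shows on the identical counts (see
`docs/methods.md`). `out/ledger.tsv` holds the four per-stage booleans for
every gene; `out/candidates.tsv` the ranked survivors (r ascending);
`out/km_high.tsv` / `out/km_low.tsv` the product-limit curves of the
score-stratified cohort.

Each stage is also exposed separately (`simulate`, `scan`, `de`, `cascade`,
`survive`, `assay` subcommands) and as plain library functions:

```python
from mir29triage import MIR29A, find_seed_sites
find_seed_sites(MIR29A, "AAUGGUGCUAAA")
# [SeedSite(gene_id='', start=2, end=10, site_type='8mer')]
```

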