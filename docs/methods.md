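# Methods

## The triage model

The package treats miR-29 target discovery as an intersection of four
independent evidence streams over a common gene universe. The stage
predicates, with their boundary semantics, are:

| stage      | predicate                                   | boundary  |
|------------|---------------------------------------------|-----------|
| mimic_down | log₂FC < −0.5 **and** FDR < 0.05            | strict    |
| cohort_up  | log₂FC ≥ 0.3 **and** FDR ≤ 0.05             | non-strict|
| sites      | n_algorithms ≥ 8 **and** conserved          | non-strict|
| anticorr   | Pearson r ≤ −0.3                            | non-strict|

Strictness is encoded exactly as the thresholds are typeset: a gene at
log₂FC = −0.5 fails stage 1, a gene at log₂FC = 0.3 passes stage 2. Genes
missing from a stream fail that stage rather than erroring, because real
support tables are sparse; every input gene is retained in the output
ledger with all four booleans. Candidates are sorted by r ascending, then
mimic log₂FC ascending, then gene id, so output files are byte-stable.
Conservation is an input flag: multi-species alignment is out of scope.
The internal seed scanner provides reproducible site evidence in the
ledger, but stage 3 gates on the external consensus votes, which is what
the selection rule specifies.

## Seed-site scanning

Canonical site taxonomy: 8mer > 7mer-m8 > 7mer-A1 > 6mer, defined from the
miRNA seed (positions 2–8). The scanner finds every occurrence of the
6-nt seed core (reverse complement of seed positions 2–7) and upgrades it
by two independent context checks: complementarity to miRNA position 8
immediately 5′ in the UTR, and an A immediately 3′ (opposite miRNA
position 1 — an identity element, not a complementarity requirement).
Each core occurrence is reported once at its maximal type; overlapping
cores at distinct offsets are all reported. Coordinates are 0-based
half-open (BED). T≡U, so DNA and RNA FASTA both work, and output echoes
the input alphabet. The packaged mature sequences are the miRBase v22
strings for hsa-miR-29a/b/c-3p; miR-29a and miR-29c differ at exactly one
position over their common 22 nt and share the seed, which is why one
scanner serves the family and why mature qPCR assays cross-react (the
latter is documented here, not simulated).

## Differential expression

Implemented from first principles (no external DE package is called at
runtime):

* **Size factors** — median-of-ratios: per-gene geometric-mean reference
  over genes with no zero, per-sample median of count/reference ratios,
  rescaled to geometric mean 1. If no gene is observed in every sample the
  code falls back to upper-quartile factors with a warning.
* **Dispersion** — per-gene method of moments on normalized counts within
  each condition, φ = max(0, (s²−μ)/μ²), averaged across conditions, then
  shrunk 50/50 toward the median raw φ of the 50 nearest genes by mean
  expression. All-zero genes get φ = NA and are excluded from testing.
* **Wald test** — log₂FC = log₂((m₂+c)/(m₁+c)) on group means of
  normalized counts with pseudocount c = 0.5; delta-method SE from
  Var(K) = μ + φμ² summed over samples; two-sided normal p-value. Genes
  with mean normalized count < 5 are excluded before testing.
* **FDR** — Benjamini–Hochberg step-up, applied within each contrast.

Numerical caveat: because the factors are renormalized to geometric mean 1
while the pseudocount is fixed, multiplying one sample's counts by k
shifts every log₂FC by ~c(k^(1/n)−1)/(μ ln 2) — about 10⁻⁴–10⁻² depending
on expression, not exactly zero. The test suite documents this achieved
invariance. The suite also cross-checks fold changes against pydeseq2 on
the same matrix (correlation, not equality: the estimators differ by
design) and BH against statsmodels and a quadratic brute-force oracle.

## Synthetic studies

Counts are negative binomial with mean μ_gs = s_s·q_g·2^(x_s·β_g) and
variance μ + φμ²: depth factors s_s log-uniform on [0.5, 2] (wide enough
that normalization is load-bearing), baselines q_g log-normal
(median 200, σ_log = 1.2), a single shared φ (default 0.1), and planted
log₂FC β_g (−1.0 under mimic, +0.6 melanoma-vs-nevus) on the first
n_targets genes. The cohort contrast additionally draws a latent standard
normal m_s per sample, standing for pri-miR-29b2~c normalized expression:
target means are multiplied by 2^(−0.5·m_s) and a matching pri-miR read
count (baseline 500) is emitted, which induces the planted
anti-correlation. Default arm sizes are 3v3 for the mimic experiment (a
design choice; the replicate number is not dictated by the emulated study)
and 23 nevi / 57 melanomas for the cohort.

UTRs are uniform-composition random sequences (200–2000 nt) scrubbed of
accidental seed cores by rejection-resampling, so planted coordinates are
the complete truth; a flag re-enables accidental sites for stress tests.
Each target receives one 8mer site at a recorded position. Predictor votes
are Binomial(12, vote_mean/12) with vote_high = 10 for targets and
vote_low = 2 otherwise, giving ≈ 97% of targets and ≪ 1% of non-targets
at least 8 votes; targets are flagged conserved, non-targets with
probability 1/2. Survival times are exponential with hazard
h₀·exp(logHR·z) on the standardized score and independent Uniform(0, 3/h₀)
censoring (~20–40% censored at defaults). Ct tables shift the target gene
by −log₂F against a flat reference with Gaussian well noise (sd 0.05,
3 replicates); luciferase tables plant a repression factor on the
wildtype-reporter ratio and a configurable rescue fraction on the
seed-mutant reporter, with log-normal channel noise.

All randomness flows from the config seed through per-call generator
streams; identical configs give byte-identical outputs. What the generator
does **not** emulate: GC/length bias, batch effects, per-gene dispersion
heterogeneity, correlated genes, read-level artifacts, informative
censoring. Passing tests therefore demonstrate the correctness and
calibration of the statistics under the declared model, not performance on
real sequencing data.

## Statistical power at the default study size

The default conditions are deliberately kept at the emulated designs, and
two consequences are worth stating plainly because the test suite encodes
them:

* **The 3v3 mimic contrast cannot reliably flag a twofold change at
  φ = 0.1.** The per-observation squared CV is ≈ 1/μ + φ, so the Wald z of
  a one-log₂-unit effect is bounded near |β| ln2 / √(2φ/3) ≈ 2.7 whatever
  the expression level, while clearing BH at FDR < 0.05 among 2000 genes
  with 9 signals needs z ≈ 3.7. Typical recovery is 0–3 of 9 targets, and
  pydeseq2 on the identical matrix recovers 1/9 — this is an information
  limit of the design, not an estimator defect. The cohort stage (23v57,
  +0.6) is powered in principle (z ≈ 5), but the latent pri-miR factor
  adds ≈ 0.13 to target squared-CV, making per-target recovery partial and
  — through BH's step-up coupling — nearly all-or-nothing across seeds.
  False positives remain at ≈ 0 throughout, so the cascade's specificity
  claim stands at desk scale; full sensitivity does not.
* **The Gehan–Breslow–Wilcoxon p-value is asymptotic.** The statistic
  (weight n_j at each event time, hypergeometric moments with tie
  correction, χ²₁ reference) matches lifelines' Wilcoxon-weighted log-rank
  to 10⁻¹², and with no censoring and distinct times its U equals minus
  the pairwise Gehan statistic. At n ≤ 8, however, the χ² tail differs
  from the exact permutation distribution by up to ~0.1 in p — the
  permutation null is discrete with ~70 atoms. Calibration is accurate at
  realistic n (null rejection 0.049 at n = 60 over 1000 replicates).

## Downstream conventions

* **Stratification** — per-gene z-scores across subjects, averaged over
  the gene set, median split with ties (and exact-median subjects)
  assigned "low"; tertile or per-gene splits were considered and rejected
  as harder to defend without a stated convention. Degenerate all-constant
  input yields all-"low" with a warning.
* **ΔΔCt** — technical replicates are averaged per sample *before* ΔCt to
  avoid inflating the replicate variance; amplification efficiency is
  fixed at 2 (configurable base). RQ is invariant to any constant Ct
  shift.
* **Luciferase** — per-sample experimental/control ratio (UTR reporter
  over co-expressed normalizer; a flag flips the orientation for other
  vector layouts), condition means normalized to a baseline condition.
  Rescue index = (mutant-UTR fold change under mimic) − (wildtype-UTR fold
  change under mimic); 0 under no effect, positive when mutation rescues.
* **Group tests** — pooled-variance unpaired two-tailed t-test and one-way
  ANOVA via scipy; t² = F on two groups is asserted to 10⁻⁹.

## Problem sizes used by the checks

The acceptance script and test suite run the scanner-vs-enumeration check
on 1000 random UTRs, DE null calibration on 20 replicates of the full
2000-gene 3v3 design, BH against the quadratic oracle on 1000 random
p-vectors, GBW null calibration on 1000 two-group studies of n = 60,
the permutation comparison at 50,000 draws, and stratified survival power
on 200 replicates of n = 200 — sizes chosen to make Monte-Carlo error
small relative to every asserted margin while keeping a laptop run in
seconds.
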