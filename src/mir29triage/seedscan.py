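"""Canonical miR-29 seed-match site detection in 3'UTR sequences.

A miRNA represses an mRNA mainly through Watson-Crick pairing between the
miRNA *seed* (nucleotides 2-8 of the mature strand) and a complementary
stretch in the mRNA 3'UTR.  Canonical sites are graded by efficacy:

    8mer     perfect match to seed positions 2-8 plus an A in the UTR
             opposite miRNA position 1
    7mer-m8  perfect match to seed positions 2-8
    7mer-A1  match to positions 2-7 plus the A opposite position 1
    6mer     match to positions 2-7 only

All three mature miR-29 family members (29a/b/c) carry the identical seed,
so one scanner serves the whole family.  UTRs are scanned on the given
(sense) strand only; DNA and RNA alphabets are both accepted with T and U
treated as equivalent, and output sequences echo the input alphabet.
Coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureMiRNA",
    "SeedSite",
    "GeneSiteSummary",
    "MIR29A",
    "MIR29B",
    "MIR29C",
    "SITE_TYPE_ORDER",
    "reverse_complement",
    "find_seed_sites",
    "scan_fasta",
    "summarize_gene_sites",
    "sites_to_bed",
    "read_support_table",
]

# Site types from strongest to weakest repression.
SITE_TYPE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")
_VALID = set("ACGTUNacgtun")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA given 5'->3' in the RNA alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"{self.name}: mature length {len(seq)} outside 18-26 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.name}: non-RNA characters {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Seed sequence: nucleotides 2-8 (1-based, inclusive), length 7."""
        return self.sequence[1:8]


# miRBase v22 mature sequences (packaged fixtures).
MIR29A = MatureMiRNA("hsa-miR-29a-3p", "UAGCACCAUCUGAAAUCGGUUA")
MIR29B = MatureMiRNA("hsa-miR-29b-3p", "UAGCACCAUUUGAAAUCAGUGUU")
MIR29C = MatureMiRNA("hsa-miR-29c-3p", "UAGCACCAUUUGAAAUCGGUUA")


@dataclass(frozen=True)
class SeedSite:
    """One classified seed-match site on a 3'UTR (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
        if self.site_type not in expected:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != expected[self.site_type]:
            raise ValueError(
                f"{self.gene_id}: span {self.end - self.start} does not match "
                f"{self.site_type}"
            )


@dataclass
class GeneSiteSummary:
    """Per-gene site tally merged with external prediction support."""

    gene_id: str
    n_sites: Mapping[str, int] = field(default_factory=dict)
    best_type: str | None = None
    n_algorithms: int = 0
    conserved: bool = False


def reverse_complement(sequence: str, rna: bool | None = None) -> str:
    """Watson-Crick reverse complement, preserving the input alphabet.

    T and U are equivalent on input.  Output uses RNA (U) if the input
    contains U or ``rna=True``, DNA (T) if it contains T or ``rna=False``;
    an alphabet-ambiguous input (no T or U) defaults to RNA.

    Raises ``ValueError`` naming the first offending position for characters
    outside {A, C, G, T, U, N}.
    """
    for i, ch in enumerate(sequence):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    upper = sequence.upper()
    if rna is None:
        rna = "T" not in upper  # U present, or ambiguous -> RNA
    rc = upper.replace("T", "U").translate(_RNA_COMPLEMENT)[::-1]
    if not rna:
        rc = rc.replace("U", "T")
    return rc


def _seed_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """The four literal site patterns implied by a seed, in RNA alphabet.

    core6 is the reverse complement of seed positions 2-7 of the miRNA
    (sequence positions 2-7, i.e. seed[0:6]); the m8 match prepends the
    complement of miRNA position 8 and the A1 variant appends an A opposite
    miRNA position 1.
    """
    seed = mirna.seed
    if len(seed) < 7:
        raise ValueError("seed shorter than 7 nt")
    core6 = reverse_complement(seed[:6], rna=True)
    m8 = reverse_complement(seed[6], rna=True)
    return {
        "6mer": core6,
        "7mer-A1": core6 + "A",
        "7mer-m8": m8 + core6,
        "8mer": m8 + core6 + "A",
    }


def find_seed_sites(mirna: MatureMiRNA, utr: str, gene_id: str = "") -> list[SeedSite]:
    """Find and classify every canonical seed-match site in a 3'UTR.

    Each occurrence of the 6-nt seed core is reported exactly once, at its
    maximal type: the core alone is a 6mer; a match to miRNA position 8
    immediately 5' in the UTR upgrades it to 7mer-m8; an A immediately 3'
    (opposite miRNA position 1) upgrades it to 7mer-A1; both together make
    an 8mer.  Overlapping sites with distinct core offsets are all reported.
    """
    for i, ch in enumerate(utr):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    pats = _seed_patterns(mirna)
    core6, m8 = pats["6mer"], pats["7mer-m8"][0]
    u = utr.upper().replace("T", "U")
    sites: list[SeedSite] = []
    for m in re.finditer(f"(?={core6})", u):
        i = m.start()
        has_m8 = i >= 1 and u[i - 1] == m8
        has_a1 = i + 6 < len(u) and u[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            site_type, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            site_type, start, end = "7mer-A1", i, i + 7
        else:
            site_type, start, end = "6mer", i, i + 6
        sites.append(SeedSite(gene_id, start, end, site_type))
    return sites


def scan_fasta(
    fasta: str | Path, mirna: MatureMiRNA = MIR29A
) -> list[SeedSite]:
    """Scan every record of a (DNA or RNA) FASTA file of 3'UTRs."""
    sites: list[SeedSite] = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        sites.extend(find_seed_sites(mirna, str(rec.seq), gene_id=rec.id))
    return sites


def read_support_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of external predictor support: gene_id, n_algorithms, conserved."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df["conserved"] = df["conserved"].astype(int)
    return df


def summarize_gene_sites(
    sites: Iterable[SeedSite], support: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tally sites per gene and merge with the external support table.

    Returns one row per gene present in either input with columns
    ``gene_id, n_8mer, n_7mer_m8, n_7mer_A1, n_6mer, best_type,
    n_algorithms, conserved``.  Genes absent from the support table get
    ``n_algorithms = 0, conserved = False``; genes in the support table with
    no scanned site keep zero counts.  Duplicate support rows are rejected.
    """
    counts: dict[str, dict[str, int]] = {}
    for s in sites:
        counts.setdefault(s.gene_id, dict.fromkeys(SITE_TYPE_ORDER, 0))
        counts[s.gene_id][s.site_type] += 1

    if support is not None and support["gene_id"].duplicated().any():
        dup = support.loc[support["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in support table: {dup!r}")

    genes = set(counts)
    if support is not None:
        genes |= set(support["gene_id"])
    sup = (
        support.set_index("gene_id")
        if support is not None
        else pd.DataFrame(columns=["n_algorithms", "conserved"])
    )

    rows = []
    for g in sorted(genes):
        c = counts.get(g, dict.fromkeys(SITE_TYPE_ORDER, 0))
        best = next((t for t in SITE_TYPE_ORDER if c[t] > 0), None)
        n_alg = int(sup.at[g, "n_algorithms"]) if g in sup.index else 0
        cons = bool(sup.at[g, "conserved"]) if g in sup.index else False
        rows.append(
            {
                "gene_id": g,
                "n_8mer": c["8mer"],
                "n_7mer_m8": c["7mer-m8"],
                "n_7mer_A1": c["7mer-A1"],
                "n_6mer": c["6mer"],
                "best_type": best,
                "n_algorithms": n_alg,
                "conserved": cons,
            }
        )
    cols = [
        "gene_id", "n_8mer", "n_7mer_m8", "n_7mer_A1", "n_6mer",
        "best_type", "n_algorithms", "conserved",
    ]
    return pd.DataFrame(rows, columns=cols)


def sites_to_bed(sites: Iterable[SeedSite]) -> str:
    """Render sites as BED6 text (chrom=gene_id, name=site_type, strand=+)."""
    lines = [
        f"{s.gene_id}\t{s.start}\t{s.end}\t{s.site_type}\t0\t+" for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
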