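"""Genotype and allele frequencies from population count tables.

A biallelic site with alleles A and G gives the three genotypes AA, AG and
GG.  Frequencies are maximum-likelihood counts-over-total estimates; the
allele frequency is the gene-counting estimate p_A = (2*AA + AG) / (2n).
A Pearson chi-square goodness-of-fit test against Hardy-Weinberg
proportions (p^2, 2pq, q^2) with one degree of freedom is provided as a
routine sanity check; no continuity correction is applied.  Display
rounding is 3 decimals; all internal arithmetic is unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from scipy import stats

GENOTYPES = ("AA", "AG", "GG")


@dataclass(frozen=True)
class GenotypeCountTable:
    """Observed genotype counts for one population."""

    population: str
    counts: dict[str, int] = field(compare=False)

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotype labels: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("population must contain at least one individual")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def count(self, genotype: str) -> int:
        return self.counts.get(genotype, 0)


@dataclass(frozen=True)
class FrequencyEstimate:
    """Genotype and allele frequencies; both maps sum to 1 before rounding."""

    population: str
    genotype_freqs: dict[str, float] = field(compare=False)
    allele_freqs: dict[str, float] = field(compare=False)
    rounding: int = 3

    def rounded(self) -> "FrequencyEstimate":
        r = self.rounding
        return FrequencyEstimate(
            self.population,
            {g: round(f, r) for g, f in self.genotype_freqs.items()},
            {a: round(f, r) for a, f in self.allele_freqs.items()},
            rounding=r,
        )


@dataclass(frozen=True)
class HweResult:
    """Pearson goodness-of-fit against Hardy-Weinberg proportions (df = 1).

    ``defined`` is False for monomorphic tables, where the test is
    meaningless (expected heterozygote count is zero).
    """

    chi_square: float
    df: int
    p_value: float
    defined: bool = True


def estimate_frequencies(table: GenotypeCountTable) -> FrequencyEstimate:
    """Counts-over-total genotype frequencies and gene-counting allele
    frequencies: p_A = (2*AA + AG) / (2n)."""
    n = table.n
    genotype_freqs = {g: table.count(g) / n for g in GENOTYPES}
    p_a = (2 * table.count("AA") + table.count("AG")) / (2 * n)
    return FrequencyEstimate(
        table.population, genotype_freqs, {"A": p_a, "G": 1.0 - p_a}
    )


def hwe_test(table: GenotypeCountTable) -> HweResult:
    """Chi-square test of the observed counts against p^2, 2pq, q^2."""
    n = table.n
    p = (2 * table.count("AA") + table.count("AG")) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HweResult(math.nan, 1, math.nan, defined=False)
    expected = {"AA": p * p * n, "AG": 2 * p * q * n, "GG": q * q * n}
    chi2 = sum(
        (table.count(g) - e) ** 2 / e for g, e in expected.items()
    )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2, 1, p_value)


def read_counts_tsv(path: Union[str, Path]) -> list[GenotypeCountTable]:
    """Read a counts table: ``population  AA  AG  GG`` (tab-separated)."""
    tables = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["population", "AA", "AG", "GG"]:
            raise ValueError(f"{path}: unexpected counts header {header}")
        for line in fh:
            pop, aa, ag, gg = line.rstrip("\n").split("\t")
            tables.append(
                GenotypeCountTable(pop, {"AA": int(aa), "AG": int(ag), "GG": int(gg)})
            )
    return tables


def write_counts_tsv(tables: list[GenotypeCountTable], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("population\tAA\tAG\tGG\n")
        for t in tables:
            fh.write(
                f"{t.population}\t{t.count('AA')}\t{t.count('AG')}\t{t.count('GG')}\n"
            )


def counts_from_genotypes(population: str, genotypes: list[str]) -> GenotypeCountTable:
    """Tally a list of diploid genotype strings ("AA"/"AG"/"GG")."""
    counts = {g: 0 for g in GENOTYPES}
    for g in genotypes:
        key = "".join(sorted(g.upper()))
        if key not in counts:
            raise ValueError(f"unknown genotype {g!r}")
        counts[key] += 1
    return GenotypeCountTable(population, counts)
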