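"""Genotype and allele frequencies of the diagnostic site in two herds.

Uses the published genotype counts of the two surveyed populations
(130 animals: 5/58/67; 32 animals: 0/12/20) plus the simulated cohorts of
analysis 01, estimates frequencies with a Hardy-Weinberg goodness-of-fit
check, and writes results/allele_frequencies.tsv.
"""

import argparse
from pathlib import Path

from yakldh import GenotypeCountTable, estimate_frequencies, hwe_test
from yakldh.popgen import read_counts_tsv

ROOT = Path(__file__).resolve().parent.parent

PUBLISHED_COUNTS = [
    GenotypeCountTable("Jiulong_observed", {"AA": 5, "AG": 58, "GG": 67}),
    GenotypeCountTable("Zhongdian_observed", {"AA": 0, "AG": 12, "GG": 20}),
]


def main(seed: int = 42) -> None:
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    tables = list(PUBLISHED_COUNTS)
    simulated = ROOT / "results" / "inputs" / "genotype_counts.tsv"
    if simulated.exists():
        tables += [
            GenotypeCountTable(t.population + "_simulated", t.counts)
            for t in read_counts_tsv(simulated)
        ]

    lines = ["population\tn\tf_AA\tf_AG\tf_GG\tp_A\tp_G\thwe_chi2\thwe_p"]
    for t in tables:
        est = estimate_frequencies(t).rounded()
        hwe = hwe_test(t)
        chi2 = f"{hwe.chi_square:.3f}" if hwe.defined else "NA"
        pv = f"{hwe.p_value:.3f}" if hwe.defined else "NA"
        g, a = est.genotype_freqs, est.allele_freqs
        lines.append(
            f"{t.population}\t{t.n}\t{g['AA']}\t{g['AG']}\t{g['GG']}\t"
            f"{a['A']}\t{a['G']}\t{chi2}\t{pv}"
        )
        print(f"{t.population:22s} n={t.n:4d}  AA/AG/GG = "
              f"{g['AA']}/{g['AG']}/{g['GG']}  p_A = {a['A']}  "
              f"HWE chi2 = {chi2} (p = {pv})")

    (outdir / "allele_frequencies.tsv").write_text("\n".join(lines) + "\n")
    print(f"\ntable -> {outdir / 'allele_frequencies.tsv'}")
    print("finding: roughly 40-50% of the large herd is heterozygous at the "
          "diagnostic site; neither herd departs from Hardy-Weinberg at the 5% level")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    main(seed=ap.parse_args().seed)
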