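"""Generate the synthetic study inputs for the downstream analyses.

Writes the cattle-like reference CDS, the canonical and ambiguity-expanded
H-subunit allele sets, the subunit proteins, the genomic template pair of
the diagnostic PCR-RFLP, and Hardy-Weinberg genotype cohorts at the stated
allele frequencies, all under results/inputs/.
"""

import argparse
from pathlib import Path

from yakldh import (
    GeneratorConfig,
    make_alleles,
    make_genomic_template,
    make_m_subunit,
    make_reference_cds,
    translate,
    write_fasta,
)
from yakldh.popgen import counts_from_genotypes, write_counts_tsv
from yakldh.synthetic_data import canonical_subunit_profiles, simulate_population

ROOT = Path(__file__).resolve().parent.parent


def main(seed: int = 42, outdir: Path | None = None) -> Path:
    outdir = outdir or ROOT / "results" / "inputs"
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=seed)

    ref = make_reference_cds(cfg)
    write_fasta([ref], outdir / "reference.fa")
    print(f"reference CDS: {len(ref)} nt, {ref.n_codons} codons "
          f"({len(translate(ref)) - 1} mature residues)")

    expanded = make_alleles(ref, "expanded", cfg)
    write_fasta(expanded, outdir / "alleles_expanded.fa")
    canonical = [make_alleles(ref, w, cfg)[0] for w in ("F", "M", "S")]
    write_fasta(canonical, outdir / "alleles_canonical.fa")
    print(f"alleles: {len(canonical)} canonical, {len(expanded)} expanded haplotypes")

    profiles = canonical_subunit_profiles(ref, cfg)
    subunits = list(profiles.values()) + [make_m_subunit(cfg)]
    write_fasta([(p.label, p.protein) for p in subunits], outdir / "subunits.fa")

    for allele in ("A", "G"):
        write_fasta(
            [(f"template_{allele}", make_genomic_template(cfg, allele))],
            outdir / f"template_{allele}.fa",
        )
    print("genomic templates written (A carries the diagnostic site)")

    tables = []
    for pop in cfg.populations:
        genotypes = simulate_population(pop.p_a, pop.n, seed=seed)
        tables.append(counts_from_genotypes(pop.name, genotypes))
        print(f"simulated {pop.name}: n={pop.n} at p_A={pop.p_a}")
    write_counts_tsv(tables, outdir / "genotype_counts.tsv")
    print(f"inputs -> {outdir}")
    return outdir


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    main(seed=args.seed)
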