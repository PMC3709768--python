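"""Constrained synthetic inputs for the whole pipeline.

Real study material (cloned cDNA alleles, a genomic amplicon region,
genotyped herds) cannot be bundled, so this module generates stand-ins
that reproduce every feature the downstream analyses depend on:

* a 334-codon coding sequence (initiator Met + 333 mature residues + stop)
  whose codons are random but constrained at six positions so that the
  documented allele states exist and encode the documented residues;
* the canonical and ambiguity-expanded allele sets of the H-subunit gene:
  six segregating nucleotide positions (53, 204, 407, 689, 700, 896), five
  of them nonsynonymous (mature residues 17, 135, 229, 233, 298) and the
  third-position change at 204 synonymous;
* a genomic template pair for the diagnostic PCR-RFLP: a 402-bp amplicon
  whose A allele carries a TaqI site cutting it into 256 + 146 bp while
  the G allele is uncut;
* Hardy-Weinberg populations at stated allele frequencies.

Unconstrained codons are drawn from a typical globular-protein residue
composition with a mildly acidic skew (so the subunit pI lands in the
realistic 5.5-7 window and the chain runs anodally at gel pH 8.8), then a
uniformly chosen synonymous codon.  Everything is reproducible from a
single integer seed.

The genomic template deliberately uses its own coordinate frame: codon
arithmetic on the coding sequence cannot place a TaqI site on the
diagnostic CDS position itself (the Arg codon context forbids it), and the
real assay amplifies an intron-containing genomic region anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from yakldh.protein_properties import SubunitProfile
from yakldh.rflp_assay import PrimerPair, RestrictionEnzyme, revcomp
from yakldh.sequences import CodingSequence, translate

# residue sampling frequencies: typical vertebrate globular protein with a
# mildly acidic skew (D+E about 14%, K+R about 8.5%)
AA_FREQUENCIES = {
    "A": 0.083, "R": 0.040, "N": 0.041, "D": 0.065, "C": 0.014,
    "Q": 0.039, "E": 0.075, "G": 0.071, "H": 0.022, "I": 0.059,
    "L": 0.096, "K": 0.045, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.069,
}

# codon constraints shared by the whole allele system (reference carries the
# ancestral cattle-like state at every segregating site):
#   codon  18 AGA Arg: CDS 53 G>A gives AAA Lys        (mature 17, Arg>Lys)
#   codon  68 GGT Gly: CDS 204 T>C gives GGC Gly       (synonymous)
#   codon 136 GTT Val: CDS 407 T>G gives GGT Gly       (mature 135, Val>Gly)
#   codon 230 GAA Glu: CDS 689 A>C gives GCA Ala       (mature 229, Glu>Ala)
#   codon 234 ATG Met: CDS 700 A>G gives GTG Val       (mature 233, Met>Val)
#   codon 299 CGA Arg: CDS 896 G>A gives CAA Gln       (mature 298, Arg>Gln)
REFERENCE_CODONS = {18: "AGA", 68: "GGT", 136: "GTT", 230: "GAA", 234: "ATG", 299: "CGA"}

#: segregating CDS positions and the per-allele-class states they take;
#: "X/Y"-style entries denote the two haplotypes of that allele class
ALLELE_STATES = {
    "F": {53: "G/A", 204: "T/C", 407: "G/T", 689: "A", 700: "A/G", 896: "A"},
    "M": {53: "G/A", 204: "T/C", 407: "T", 689: "A", 700: "A/G", 896: "G"},
    "S": {53: "G", 204: "C", 407: "T", 689: "C", 700: "A", 896: "G"},
    "cattle": {53: "G", 204: "T", 407: "T", 689: "A", 700: "A", 896: "G"},
}

#: the two charge-relevant substitutions defining the canonical alleles
CANONICAL_SUBSTITUTIONS = {"F": (896, "A"), "S": (689, "C")}

#: diagnostic exon-7 primer pair of the G896A PCR-RFLP assay
DIAGNOSTIC_PRIMERS = PrimerPair(
    forward="TGCAGTTCGTCCTGTTCAAC",
    reverse="CAAGCATGGGCTTTGATTCT",
)

_TAQI = RestrictionEnzyme("TaqI", "TCGA", 1)

_SYNONYMOUS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _SYNONYMOUS.setdefault(aa, []).append(codon)
for codons in _SYNONYMOUS.values():
    codons.sort()


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    p_a: float
    n: int


@dataclass(frozen=True)
class GeneratorConfig:
    """The stated world: sizes, allele states, assay geometry, populations."""

    seed: int = 42
    n_codons: int = 334                      # initiator Met + 333 mature residues
    amplicon_length: int = 402
    cut_fragments: tuple[int, int] = (256, 146)
    left_flank: int = 100
    right_flank: int = 80
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("Jiulong", 0.262, 130),
        PopulationSpec("Zhongdian", 0.188, 32),
    )
    allele_states: dict = field(default_factory=lambda: ALLELE_STATES, compare=False)

    def __post_init__(self) -> None:
        if self.n_codons < max(REFERENCE_CODONS) + 1:
            raise ValueError("CDS too short for the constrained codons")
        if sum(self.cut_fragments) != self.amplicon_length:
            raise ValueError("cut fragments must sum to the amplicon length")


def _sample_codon(aa: str, rng: np.random.Generator) -> str:
    choices = _SYNONYMOUS[aa]
    return choices[rng.integers(len(choices))]


def make_reference_cds(config: GeneratorConfig | None = None) -> CodingSequence:
    """Cattle-like reference CDS: 1005 nt, random codons except the six
    constrained loci, no internal stop, reproducible per seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    aas = list(AA_FREQUENCIES)
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    codons = []
    for idx in range(1, config.n_codons + 1):
        if idx == 1:
            codons.append("ATG")
        elif idx in REFERENCE_CODONS:
            codons.append(REFERENCE_CODONS[idx])
        else:
            aa = aas[rng.choice(len(aas), p=probs)]
            codons.append(_sample_codon(aa, rng))
    return CodingSequence("cattle", "".join(codons) + "TAA")


def _apply_states(
    reference: CodingSequence, states: dict[int, str], which: int, new_id: str
) -> CodingSequence:
    """Apply one haplotype (first or second state of each pair) of an allele
    class to the reference."""
    seq = reference
    for pos, state in sorted(states.items()):
        options = state.split("/")
        base = options[min(which, len(options) - 1)]
        seq = seq.with_substitution(pos, base, new_id=new_id)
    return seq


def make_alleles(
    reference: CodingSequence,
    which: str = "expanded",
    config: GeneratorConfig | None = None,
) -> list[CodingSequence]:
    """Allele sequences built on the reference backbone.

    ``which`` in {"F", "M", "S"} returns the canonical single-substitution
    allele (M is protein-identical to the reference; F adds 896 G>A, S adds
    689 A>C); ``"cattle"`` returns the reference itself; ``"expanded"``
    returns the haplotype set realizing every recorded state (two
    haplotypes per ambiguous allele class plus the single S haplotype).
    """
    config = config or GeneratorConfig()
    states = config.allele_states
    if which == "cattle":
        return [reference]
    if which in CANONICAL_SUBSTITUTIONS:
        pos, base = CANONICAL_SUBSTITUTIONS[which]
        return [reference.with_substitution(pos, base, new_id=which)]
    if which == "M":
        return [CodingSequence("M", reference.bases)]
    if which == "expanded":
        out = []
        for label, st in states.items():
            if label == "cattle":
                continue
            n_haps = max(len(s.split("/")) for s in st.values())
            for hap in range(n_haps):
                suffix = f"_{hap + 1}" if n_haps > 1 else "_1"
                out.append(_apply_states(reference, st, hap, f"{label}{suffix}"))
        return out
    raise ValueError(f"unknown allele selector {which!r}")


def canonical_subunit_profiles(
    reference: CodingSequence, config: GeneratorConfig | None = None
) -> dict[str, SubunitProfile]:
    """H-subunit profiles Hf, Hm, Hs of the canonical alleles (mature chain,
    initiator Met removed)."""
    profiles = {}
    for label in ("F", "M", "S"):
        (allele,) = make_alleles(reference, label, config)
        mature = translate(allele)[1:]
        profiles["H" + label.lower()] = SubunitProfile("H" + label.lower(), mature)
    return profiles


def make_m_subunit(config: GeneratorConfig | None = None) -> SubunitProfile:
    """Synthetic stand-in for the muscle (M) subunit of the heterotetramers.

    A random 331-residue chain with a basic-shifted composition (K+R
    boosted, D+E reduced), giving the higher pI / slower anodal migration
    that places the M-rich isozymes behind the H-rich ones on the gel.  It
    emulates no feature of the real muscle-subunit sequence beyond size and
    charge class.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 1_000_003)
    freqs = dict(AA_FREQUENCIES)
    freqs["D"] = 0.040
    freqs["E"] = 0.050
    freqs["K"] = 0.075
    freqs["R"] = 0.065
    aas = list(freqs)
    probs = np.array(list(freqs.values()))
    probs = probs / probs.sum()
    protein = "".join(aas[rng.choice(len(aas), p=probs)] for _ in range(331))
    return SubunitProfile("M", protein)


def _scrub_sites(
    seq: list[str],
    enzyme: RestrictionEnzyme,
    protected: set[int],
    rng: np.random.Generator,
) -> None:
    """Destroy accidental recognition sites in place, never touching
    protected offsets."""
    while True:
        actionable = []
        for h in enzyme.sites_in("".join(seq)):
            free = [
                i for i in range(h, h + len(enzyme.recognition))
                if i not in protected
            ]
            if free:
                actionable.append((h, free))
        if not actionable:
            break
        for h, free in actionable:
            i = free[rng.integers(len(free))]
            current = seq[i]
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[current]


def make_genomic_template(
    config: GeneratorConfig | None = None, allele: str = "A"
) -> str:
    """Genomic-like template for the diagnostic PCR-RFLP.

    Layout (1-based template coordinates, fixed by construction): forward
    primer at 101-120, reverse-primer binding site at 483-502, so the
    amplicon spans 101-502 (402 bp).  The diagnostic TaqI context sits so
    that the A-allele amplicon cuts into 256 + 146 bp from the forward end;
    the G allele differs only at the last site base (TCGG) and is uncut.
    Accidental TaqI sites inside the amplicon and extra primer matches are
    scrubbed, so the assay is clean by construction.
    """
    config = config or GeneratorConfig()
    if allele not in ("A", "G"):
        raise ValueError("allele must be 'A' or 'G'")
    rng = np.random.default_rng(config.seed + 2_000_003)
    primers = DIAGNOSTIC_PRIMERS
    fwd = primers.forward
    rc_rev = revcomp(primers.reverse)
    total = config.left_flank + config.amplicon_length + config.right_flank
    bases = "ACGT"
    seq = [bases[rng.integers(4)] for _ in range(total)]
    amp_start = config.left_flank                      # 0-based amplicon start
    # primer binding sites
    seq[amp_start : amp_start + len(fwd)] = list(fwd)
    rev_start = amp_start + config.amplicon_length - len(rc_rev)
    seq[rev_start : rev_start + len(rc_rev)] = list(rc_rev)
    # diagnostic site: left cut fragment of 256 bp means the cut falls after
    # amplicon base 256, i.e. the TaqI T occupies amplicon position 256
    site_start = amp_start + config.cut_fragments[0] - 1
    seq[site_start : site_start + 4] = list("TCG" + allele)
    protected = set(range(amp_start, amp_start + len(fwd)))
    protected |= set(range(rev_start, rev_start + len(rc_rev)))
    protected |= set(range(site_start, site_start + 4))
    # no stray TaqI sites inside the amplicon (flanks are never digested)
    amp_range = range(amp_start, amp_start + config.amplicon_length)
    amp_protected = {i - amp_start for i in protected if i in amp_range}
    amp = seq[amp_start : amp_start + config.amplicon_length]
    _scrub_sites(amp, _TAQI, amp_protected, rng)
    seq[amp_start : amp_start + config.amplicon_length] = amp
    # unique primer matches on the full template
    template = "".join(seq)
    for probe, keep in ((fwd, amp_start), (rc_rev, rev_start)):
        start = 0
        while True:
            hit = template.find(probe, start)
            if hit == -1:
                break
            if hit != keep:
                free = [
                    i for i in range(hit, hit + len(probe)) if i not in protected
                ]
                i = free[rng.integers(len(free))]
                seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
                template = "".join(seq)
                start = 0
            else:
                start = hit + 1
    return template


def simulate_population(
    p_a: float, n: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """Draw n diploid genotypes at Hardy-Weinberg proportions.

    Genotypes are returned as strings in {"AA", "AG", "GG"} with
    probabilities (p^2, 2pq, q^2); reproducible for a given seed.
    """
    if not 0.0 <= p_a <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    q = 1.0 - p_a
    probs = [p_a * p_a, 2 * p_a * q, q * q]
    draws = rng.choice(3, size=n, p=probs)
    labels = np.array(["AA", "AG", "GG"])
    return list(labels[draws])


def genotype_fragments(
    genotype: str,
    config: GeneratorConfig | None = None,
    primers: PrimerPair = DIAGNOSTIC_PRIMERS,
    enzyme: RestrictionEnzyme = _TAQI,
) -> set[int]:
    """Pooled digest fragment lengths of one diploid genotype.

    Amplifies and digests the template of each of the two alleles and
    pools the fragment lengths, as co-amplification in one tube would.
    """
    from yakldh.rflp_assay import digest, find_amplicon

    config = config or GeneratorConfig()
    fragments: set[int] = set()
    for base in genotype.upper():
        template = make_genomic_template(config, allele=base)
        amp = find_amplicon(template, primers)
        fragments |= set(digest(amp, enzyme).fragment_lengths)
    return fragments
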