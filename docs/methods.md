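# Methods

`yakldh` models the computational chain behind an isozyme-electrophoresis
polymorphism study of the lactate dehydrogenase (LDH) H subunit: allelic
coding-sequence comparison, codon/residue mapping, theoretical subunit
properties, tetramer band-pattern prediction on native PAGE, in-silico
PCR-RFLP genotyping, and population allele-frequency estimation.  This note
documents the models, their assumptions, the defaults, and what the
synthetic data do and do not establish.

## Coordinate conventions

Nucleotide positions are 1-based on the coding sequence (CDS), position 1 =
the A of the initiator ATG.  Residue positions are *mature* (initiator Met
excluded): CDS position p lies in codon ceil(p/3), and the mature residue
index is the codon index minus one.  Structural literature often numbers
from the initiator Met; `CodonLocus.residue_number(met_included=True)`
provides that rendering, but every table the package emits uses mature
numbering.  Indels are out of scope — allele sets must be equal-length,
in-frame sequences, and no alignment is attempted.

## The allele system

The stated world is a 334-codon H-subunit CDS (Met + 333 mature residues +
stop) with six segregating positions: 53, 204, 407, 689, 700 and 896.
Five are nonsynonymous (mature residues 17, 135, 229, 233, 298); the
third-position change at 204 is synonymous.  Two of the substitutions
change charged residues and define the electrophoretic alleles:

* **F (fast)** — 896 G>A, Arg298Gln (`lose_positive`): one positive charge
  fewer, the subunit runs faster toward the anode.
* **S (slow)** — 689 A>C, Glu229Ala (`lose_negative`): one negative charge
  fewer, the subunit runs slower.
* **M (medium)** — the cattle-like reference protein.

Canonical alleles are minimal single-substitution haplotypes; that choice
is forced by the published mass differences (Arg>Gln removes
156.19 − 128.13 = 28.06 Da; Glu>Ala removes 129.12 − 71.08 = 58.04 Da,
both reproduced exactly by the generator).  The "G/A"-style states at the
other sites are treated as two haplotypes of the same named allele class;
the ambiguity-expanded set realizes every recorded state.  A documented
textual inconsistency in the source material about the direction at 689
("C to A" in prose vs. cattle/M/F = A, S = C in the state table) is
resolved in favour of the state table: the S allele carries C.

A substitution that flips charge sign (acidic ↔ basic) is classified as
the *gain* of the new class — the dominant electrophoretic effect; no such
substitution occurs in the shipped allele system.

## Protein properties

Average molecular weight is the sum of ExPASy average residue masses plus
one water (18.015 Da).  Net charge is the classical
Henderson–Hasselbalch sum over the free termini and the side chains of
D, E, C, Y (acidic) and H, K, R (basic); Cys is treated as a free thiol
and no post-translational modification or structure-corrected pKa shift is
modelled.  The shipped default pKa set is the Bjellqvist/ExPASy
convention simplified to residue-independent termini (N-term 7.50, C-term
3.55; D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0); any value
can be overridden from config.  On long chains the simplification is
negligible, and on sequences whose termini take no residue-specific
correction the computed pI matches Biopython's Bjellqvist implementation
to better than 1e-3 (tested).

The isoelectric point is found by bisection on (0, 14).  The charge is
strictly decreasing in pH, so the root exists and is unique.  The pH
bracket (1e-4) is the primary stopping rule; a charge-based early exit
exists but is deliberately conservative (1e-6), because on charge-flat
peptides a loose charge tolerance would stop milli-pH-units from the root.
Bisection agrees with an independent 10001-point grid-scan oracle to
within 1e-3.

## Tetramer model and gel mobility

LDH is a random-assembly tetramer of H and M subunits; isozyme class k
(LDH1..LDH5) has h = 5 − k H slots.  With s distinct H-subunit species a
class splits into C(h+s−1, s−1) compositions — 5/4/3/2/1 forms for a
two-allele heterozygote — with multinomial intensities from the expression
weights.  Equal allelic expression (0.5/0.5) is the default for
heterozygotes; no expression data are modelled.

Mobility is scored as −(Σ subunit net charges at gel pH)/(Σ subunit
MW)^(2/3) at the native-PAGE running pH 8.8, a deliberately crude
free-solution approximation (no Ferguson/sieving model): only the rank
order of bands and the relative gap sizes are ever interpreted, never
absolute migration distances.  Within each class, adjacent bands closer
than the merge threshold collapse into one broad band (intensity summed,
intensity-weighted mean mobility, the merge logged).  The default
threshold, 5e-4 mobility units, is calibrated between the two physical
regimes for ~36.5 kDa subunits: subunit pairs one charge unit apart (F/M
or M/S) space their class-1 bands ~3.6e-4 apart and merge into a broad
band, pairs two charge units apart (F/S) space them ~7.2e-4 apart and
resolve into the full ladder.  Both regimes are what the corresponding
wet-lab gels show.  Observed band broadening may additionally reflect
post-translational microheterogeneity; the model attributes it to
co-migrating heterotetramers only.

`classify_phenotype` maps diploid states at 896/689 to the phenotype
labels: any F allele shows the fast band (F), except the F/S compound
whose strongly separated subunits produce the multi-band phenotype
("multiple").  The M/S compound also carries two charge-distinct H
subunits and is likewise reported as "multiple" — a gap-fill decision, as
the source phenotype table never observed that genotype.  When both sites
are heterozygous the phase is ambiguous and haplotypes must be supplied.

## PCR-RFLP

Primers are matched exactly (no mismatch tolerance or Tm model), the
reverse primer as the reverse complement downstream of the forward match;
exactly one product is required.  Restriction sites are matched with full
IUPAC ambiguity, overlapping occurrences all cut, and cut positions follow
the **top-strand** convention (TaqI T^CGA cuts after the T).  One
consequence worth knowing: digesting the reverse complement with a
staggered palindromic cutter reverses the fragment list only up to the
overhang (2 nt for TaqI); for blunt cutters the reversal is exact.
Genotypes are called from pooled fragment lengths with a ±2% relative
tolerance emulating gel-sizing error: cut pattern only → homozygous cut
allele, uncut only → homozygous uncut, union → heterozygote, anything
else → uninterpretable.  The enzyme catalog is a small shipped table of 20
common enzymes, not a live REBASE dependency.

## Synthetic data: what it is and is not

The generator emits the stated world from one integer seed: unconstrained
codons are drawn from a typical globular-protein residue composition with
a mildly acidic skew (D+E ≈ 14%, K+R ≈ 8.5%), chosen so the H subunit is
reliably negative at gel pH 8.8 with a pI in a realistic acidic window;
the six constrained codons (AGA-18, GGT-68, GTT-136, GAA-230, ATG-234,
CGA-299) realize the documented allele states and residue changes.  The
backbone is random, so *absolute* pI and MW vary by seed and are never
asserted — only the substitution-induced deltas, orders and charge
differences, which are seed-independent, carry meaning.  Reproducing the
published absolute subunit values (pI 5.87/6.03/6.21, MW
36564.39/36592.45/36534.41 Da) would require the real database sequences,
which this offline package does not bundle; the package asserts the exact
mass deltas (28.06/58.04 Da) and the pI order/direction instead.

The genomic template places the diagnostic primers so the amplicon is
exactly 402 bp with the TaqI context positioned to cut the A allele into
256 + 146 bp; accidental sites and stray primer matches are scrubbed.  The
template deliberately has its own coordinate frame: codon arithmetic
cannot place a TaqI site on the diagnostic CDS position itself (the Arg
codon context forbids TCGA there), and the real assay amplifies an
intron-containing genomic region in any case.  The M-subunit stand-in is
a random basic-shifted 331-mer (pI ≈ 9.7 at seed 42) — deliberately more
basic than a real muscle subunit (~8.4) so that H/M class separation is
robust at any seed; only rank order is interpreted.

Populations are drawn at exact Hardy–Weinberg proportions with no
inbreeding, structure, or genotyping error.  A green genotyping round-trip
therefore establishes internal consistency of the assay model, not
robustness to real gel artefacts.

## Statistics

Genotype frequencies are counts over total; the allele frequency is the
gene-counting estimate p = (2·AA + AG)/(2n), which satisfies
p = f(AA) + f(AG)/2 identically.  The Hardy–Weinberg check is a Pearson
chi-square against (p², 2pq, q²)·n with 1 df and no continuity
correction — a routine sanity check, not a published claim; it is flagged
undefined for monomorphic tables.  Display rounding is 3 decimals;
internal arithmetic is unrounded.  On 1000 simulated herds of n = 130 at
p = 0.262 the estimator's mean is within Monte-Carlo error of the truth
and the chi-square test rejects at the nominal 5% level about 3–6% of the
time (slightly conservative on discrete counts at this sample size).

## Known limitations

* No indels, alignment, splice forms, or codon-usage statistics.
* No monoisotopic masses, disulfides, or structure-corrected pKas.
* The mobility model ignores gel sieving; merge behaviour is calibrated,
  not fitted to densitometry.
* Primer matching is exact; partial digestion and star activity are not
  modelled.
* Linkage between the two diagnostic sites is not estimated (no joint
  counts are consumed anywhere).
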