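"""Tetramer isozyme combinatorics and native-PAGE band prediction.

LDH is a tetramer assembled from H and M subunits; the five somatic
isozymes LDH1..LDH5 carry 4,3,2,1,0 H subunits respectively.  When a
heterozygote expresses two (or more) distinct H subunits, random assembly
splits each isozyme class into several co-migrating species: class k with
h = 5 - k H slots and s H-subunit species yields C(h+s-1, s-1) distinct
tetramer compositions, with multinomial relative intensities.

Electrophoretic mobility is modelled as net charge over size,
score = -(sum of subunit charges at gel pH) / (sum of subunit MW)^(2/3),
a deliberately simple free-solution approximation: only the rank order and
the gap sizes of bands are interpreted, never absolute migration distances.
Bands closer than a merge threshold are collapsed into one "broad band",
reproducing the experimentally familiar regimes where subunits of similar
charge smear into a single wide band while strongly different subunits
resolve into a ladder of discrete bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import factorial
from typing import Iterable, Sequence

from yakldh.protein_properties import SubunitProfile

#: default native-gel running pH (Tris-glycine system)
GEL_PH = 8.8

#: default mobility-gap threshold below which adjacent bands appear as one
#: broad band.  Calibrated (in mobility-score units, for ~36.5 kDa subunits)
#: between the one-charge-unit and two-charge-unit per-subunit regimes, so
#: that a subunit pair differing by one charge unit merges and a pair
#: differing by two resolves.
MERGE_THRESHOLD = 5e-4

ISOZYME_CLASSES = (1, 2, 3, 4, 5)


class PhasingError(ValueError):
    """Genotype cannot be interpreted without haplotype phase."""


@dataclass(frozen=True)
class SubunitPool:
    """The subunit species available for tetramer assembly in one animal.

    ``h_species`` carries the H-subunit variants with their expression
    weights (fractions summing to 1); ``m_species`` is the single M
    subunit.  Equal allelic expression (0.5/0.5) is the default for
    heterozygotes.
    """

    h_species: tuple[tuple[SubunitProfile, float], ...]
    m_species: SubunitProfile

    def __post_init__(self) -> None:
        if not self.h_species:
            raise ValueError("need at least one H species")
        weights = [w for _, w in self.h_species]
        if any(w < 0 for w in weights):
            raise ValueError("expression weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("H-species weights must sum to 1")

    @classmethod
    def from_profiles(
        cls,
        h_profiles: Sequence[SubunitProfile],
        m_profile: SubunitProfile,
        weights: Sequence[float] | None = None,
    ) -> "SubunitPool":
        if weights is None:
            weights = [1.0 / len(h_profiles)] * len(h_profiles)
        return cls(tuple(zip(h_profiles, weights)), m_profile)

    @property
    def profiles(self) -> dict[str, SubunitProfile]:
        d = {p.label: p for p, _ in self.h_species}
        d[self.m_species.label] = self.m_species
        return d


@dataclass(frozen=True)
class IsozymeBand:
    """One (possibly merged) band: tetramer composition(s), mobility, intensity."""

    isozyme_class: int
    composition: tuple[str, ...]
    mobility: float
    intensity: float
    merged_from: tuple[tuple[str, ...], ...] = ()

    @property
    def is_broad(self) -> bool:
        return len(self.merged_from) > 1

    @property
    def label(self) -> str:
        def fmt(comp: tuple[str, ...]) -> str:
            out, seen = [], []
            for lab in comp:
                if lab not in seen:
                    seen.append(lab)
                    n = comp.count(lab)
                    out.append(lab if n == 1 else f"{lab}{n}")
            return "".join(out)

        if self.is_broad:
            return "+".join(fmt(c) for c in self.merged_from)
        return fmt(self.composition)


@dataclass(frozen=True)
class GelPattern:
    """Predicted lane: bands sorted by descending mobility, with merge log."""

    sample_id: str
    bands: tuple[IsozymeBand, ...]
    merge_events: tuple[tuple[tuple[str, ...], ...], ...] = ()

    def bands_in_class(self, isozyme_class: int) -> list[IsozymeBand]:
        return [b for b in self.bands if b.isozyme_class == isozyme_class]


def multiset_coefficient(h: int, s: int) -> int:
    """Number of size-h multisets from s species: C(h+s-1, s-1)."""
    return factorial(h + s - 1) // (factorial(h) * factorial(s - 1))


def enumerate_tetramers(
    n_h_species: int, isozyme_class: int
) -> list[tuple[int, ...]]:
    """All distinct H-slot fillings of one isozyme class.

    Class k has h = 5 - k H slots (the remaining slots take the single M
    species); returns the multisets of H-species indices, lexicographically
    sorted.  For class 5 (M4) the single empty filling is returned.
    """
    if n_h_species < 1:
        raise ValueError("need at least one H species")
    if isozyme_class not in ISOZYME_CLASSES:
        raise ValueError(f"isozyme class must be in 1..5, got {isozyme_class}")
    h = 5 - isozyme_class
    return list(combinations_with_replacement(range(n_h_species), h))


def _multinomial_prob(counts: Iterable[int], weights: Sequence[float]) -> float:
    counts = list(counts)
    n = sum(counts)
    coeff = factorial(n)
    p = 1.0
    for k, w in zip(counts, weights):
        coeff //= factorial(k)
        p *= w**k
    return coeff * p


def band_intensities(
    pool: SubunitPool, isozyme_class: int
) -> dict[tuple[int, ...], float]:
    """Relative intensity of each tetramer composition within one class.

    Random assembly: the h H slots are filled independently from the
    species expression weights, so each multiset gets its multinomial
    probability; intensities sum to 1 per class.
    """
    weights = [w for _, w in pool.h_species]
    h = 5 - isozyme_class
    out = {}
    for comp in enumerate_tetramers(len(pool.h_species), isozyme_class):
        counts = [comp.count(i) for i in range(len(weights))]
        out[comp] = _multinomial_prob(counts, weights) if h > 0 else 1.0
    return out


def mobility_score(
    composition: Sequence[str],
    profiles: dict[str, SubunitProfile],
    gel_pH: float = GEL_PH,
) -> float:
    """Anodal mobility score of a tetramer composition (higher = faster).

    score = -(sum of subunit net charges at gel pH) / (sum of subunit MW)^(2/3).
    Invariant under permutation of the composition multiset.
    """
    missing = [lab for lab in composition if lab not in profiles]
    if missing:
        raise KeyError(f"no profile for subunit label(s) {sorted(set(missing))}")
    total_q = sum(profiles[lab].net_charge_at(gel_pH) for lab in composition)
    total_mw = sum(profiles[lab].mw for lab in composition)
    return -total_q / total_mw ** (2.0 / 3.0)


def _merge_adjacent(
    bands: list[IsozymeBand], threshold: float
) -> tuple[list[IsozymeBand], list[tuple[tuple[str, ...], ...]]]:
    """Collapse runs of bands whose successive mobility gaps are < threshold."""
    merged, events = [], []
    i = 0
    while i < len(bands):
        group = [bands[i]]
        while i + 1 < len(bands) and abs(
            bands[i].mobility - bands[i + 1].mobility
        ) < threshold:
            i += 1
            group.append(bands[i])
        if len(group) == 1:
            merged.append(group[0])
        else:
            total = sum(b.intensity for b in group)
            mob = sum(b.mobility * b.intensity for b in group) / total
            comps = tuple(b.composition for b in group)
            merged.append(
                IsozymeBand(
                    isozyme_class=group[0].isozyme_class,
                    composition=group[0].composition,
                    mobility=mob,
                    intensity=total,
                    merged_from=comps,
                )
            )
            events.append(comps)
        i += 1
    return merged, events


def render_pattern(
    pool: SubunitPool,
    merge_threshold: float = MERGE_THRESHOLD,
    gel_pH: float = GEL_PH,
    sample_id: str = "sample",
    classes: Sequence[int] = ISOZYME_CLASSES,
) -> GelPattern:
    """Predict the full lane for one subunit pool.

    Per isozyme class: enumerate compositions, score and sort by mobility,
    then merge adjacent bands closer than ``merge_threshold`` into broad
    bands (intensity summed, intensity-weighted mean mobility, the merge
    recorded).  Merging never crosses isozyme classes.
    """
    h_labels = [p.label for p, _ in pool.h_species]
    m_label = pool.m_species.label
    profiles = pool.profiles
    all_bands: list[IsozymeBand] = []
    events: list[tuple[tuple[str, ...], ...]] = []
    for k in classes:
        intens = band_intensities(pool, k)
        bands = []
        for comp_idx, intensity in intens.items():
            labels = tuple(h_labels[i] for i in comp_idx) + (m_label,) * (k - 1)
            bands.append(
                IsozymeBand(
                    isozyme_class=k,
                    composition=labels,
                    mobility=mobility_score(labels, profiles, gel_pH),
                    intensity=intensity,
                )
            )
        bands.sort(key=lambda b: -b.mobility)
        bands, ev = _merge_adjacent(bands, merge_threshold)
        all_bands.extend(bands)
        events.extend(ev)
    all_bands.sort(key=lambda b: -b.mobility)
    return GelPattern(sample_id, tuple(all_bands), tuple(events))


def _haplotype_class(base_896: str, base_689: str) -> str:
    table = {("A", "A"): "F", ("G", "A"): "M", ("G", "C"): "S"}
    try:
        return table[(base_896.upper(), base_689.upper())]
    except KeyError:
        raise ValueError(
            f"non-canonical haplotype 896{base_896}/689{base_689}"
        ) from None


def classify_phenotype(
    genotype_896: Sequence[str],
    genotype_689: Sequence[str],
    haplotypes: Sequence[tuple[str, str]] | None = None,
) -> str:
    """LDH1 phenotype from the diploid states at the two diagnostic sites.

    CDS 896 G>A distinguishes the fast allele (A, Gln298) from G alleles;
    among the latter CDS 689 A>C distinguishes the slow allele (C, Ala229)
    from the cattle-like M allele.  Any F allele is electrophoretically
    dominant (F band visible) except in the F/S compound, whose two
    strongly charge-separated subunits yield the multi-band phenotype.
    The M/S compound also carries two distinct H subunits and is likewise
    reported as ``"multiple"``.

    If both sites are heterozygous the genotype is uninterpretable without
    phase and ``haplotypes`` (two (base896, base689) pairs) is required.
    """
    g896 = tuple(b.upper() for b in genotype_896)
    g689 = tuple(b.upper() for b in genotype_689)
    if len(g896) != 2 or len(g689) != 2:
        raise ValueError("genotypes must be diploid (two bases per site)")
    if haplotypes is not None:
        haps = [tuple(h) for h in haplotypes]
        if len(haps) != 2:
            raise ValueError("exactly two haplotypes expected")
        if sorted(h[0] for h in haps) != sorted(g896) or sorted(
            h[1] for h in haps
        ) != sorted(g689):
            raise ValueError("haplotypes inconsistent with site genotypes")
    elif len(set(g896)) > 1 and len(set(g689)) > 1:
        raise PhasingError(
            "both diagnostic sites heterozygous: haplotypes required to "
            "resolve the phenotype"
        )
    else:
        # phase is forced when at most one site is heterozygous
        hom_689 = g689[0] if len(set(g689)) == 1 else None
        if hom_689 is not None:
            haps = [(b, hom_689) for b in g896]
        else:
            haps = [(g896[0], b) for b in g689]
    classes = {_haplotype_class(b896, b689) for b896, b689 in haps}
    if len(classes) == 2 and "F" not in classes:
        return "multiple"  # M/S compound: two distinct H subunits
    if classes == {"F", "S"}:
        return "multiple"
    if "F" in classes:
        return "F"
    return classes.pop()
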