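"""In-silico PCR-RFLP: amplification, restriction digestion, genotype calls.

Primers are matched exactly (no mismatch tolerance, no melting-temperature
model); recognition sites honour IUPAC ambiguity codes and overlapping
occurrences all cut.  Coordinates on amplicons are 1-based inclusive and
fragments are reported template left-to-right.  The enzyme catalog is a
small shipped table, not a live REBASE dependency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class PcrError(ValueError):
    """Amplification failed (no product or nonspecific)."""


class NoProductError(PcrError):
    pass


class NonspecificError(PcrError):
    def __init__(self, loci: list[tuple[int, int]]):
        self.loci = loci
        super().__init__(
            f"nonspecific amplification: {len(loci)} products at loci {loci}"
        )


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primer, both written 5'->3' on their own strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{name} primer shorter than 15 nt")
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{name} primer contains non-ACGT characters")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II enzyme: recognition site (IUPAC) and top-strand cut offset.

    ``cut_offset`` counts bases of the site left of the cut, e.g. TaqI
    T^CGA has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        if len(site) < 4:
            raise ValueError("recognition site shorter than 4 nt")
        if set(site) - set(IUPAC):
            raise ValueError(f"invalid IUPAC characters in site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut offset outside recognition site")
        object.__setattr__(self, "recognition", site)

    @property
    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all found
        body = "".join(
            b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in self.recognition
        )
        return re.compile(f"(?={body})")

    def is_palindromic(self) -> bool:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A",
                "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
                "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}
        return self.recognition == "".join(
            comp[b] for b in reversed(self.recognition)
        )

    def sites_in(self, seq: str) -> list[int]:
        """0-based start positions of all (overlapping) site occurrences."""
        return [m.start() for m in self.regex.finditer(seq.upper())]


def load_enzyme_catalog(path: Union[str, Path, None] = None) -> dict[str, RestrictionEnzyme]:
    """Load the shipped enzyme table (or a user TSV: name, site, offset)."""
    if path is None:
        text = files("yakldh.data").joinpath("enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = text.strip().splitlines()
    if lines[0].split("\t") != ["name", "recognition", "cut_offset"]:
        raise ValueError("enzyme catalog header must be: name recognition cut_offset")
    catalog = {}
    for line in lines[1:]:
        name, site, offset = line.split("\t")
        catalog[name] = RestrictionEnzyme(name, site, int(offset))
    return catalog


@dataclass(frozen=True)
class Amplicon:
    """A PCR product with its 1-based inclusive template coordinates."""

    sequence: str
    start: int
    end: int

    def __len__(self) -> int:
        return len(self.sequence)


def find_amplicon(template: str, primers: PrimerPair) -> Amplicon:
    """Exact-match PCR: unique forward match, unique downstream reverse match.

    The forward primer is located on the plus strand and the reverse
    complement of the reverse primer downstream of it; the amplicon spans
    the first base of the forward match to the last base of the reverse
    match, inclusive.  Zero candidate products raise
    :class:`NoProductError`; more than one raise :class:`NonspecificError`
    listing all loci.
    """
    template = template.upper()
    fwd, rc_rev = primers.forward, revcomp(primers.reverse)
    fwd_hits = [m.start() for m in re.finditer(f"(?={re.escape(fwd)})", template)]
    rev_hits = [m.start() for m in re.finditer(f"(?={re.escape(rc_rev)})", template)]
    products = [
        (f, r)
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(fwd)
    ]
    if not products:
        raise NoProductError("no product: primer pair does not amplify template")
    if len(products) > 1:
        raise NonspecificError(
            [(f + 1, r + len(rc_rev)) for f, r in products]
        )
    f, r = products[0]
    end = r + len(rc_rev)
    return Amplicon(template[f:end], f + 1, end)


@dataclass(frozen=True)
class DigestResult:
    """Fragments of one digestion, left to right on the amplicon.

    ``cut_positions`` are 1-based: a cut at position p falls between bases
    p and p+1.
    """

    fragment_lengths: tuple[int, ...]
    cut_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(length < 1 for length in self.fragment_lengths):
            raise ValueError("fragments must be >= 1 bp")


def digest(amplicon: Union[str, Amplicon], enzyme: RestrictionEnzyme) -> DigestResult:
    """Cut a linear amplicon at every recognition-site occurrence.

    Zero sites yield a single full-length fragment.  Cut positions falling
    on the very ends of the molecule (offset 0 sites at position 1, or
    offset-at-end sites at the last base) produce no physical cut.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    seq = seq.upper()
    cuts = sorted(
        {
            start + enzyme.cut_offset
            for start in enzyme.sites_in(seq)
            if 0 < start + enzyme.cut_offset < len(seq)
        }
    )
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragments, tuple(cuts))


@dataclass(frozen=True)
class RflpAssay:
    """Expected fragment patterns of a diagnostic digest.

    ``cut_pattern`` is what the allele carrying the site yields,
    ``uncut_pattern`` what the site-free allele yields; the allele labels
    default to the A-creates-site / G-lacks-site convention of a G>A
    site-creating variant.
    """

    cut_pattern: tuple[int, ...]
    uncut_pattern: tuple[int, ...]
    cut_allele: str = "A"
    uncut_allele: str = "G"

    def __post_init__(self) -> None:
        if sorted(self.cut_pattern) == sorted(self.uncut_pattern):
            raise ValueError("assay patterns must be distinct")


def _patterns_match(
    observed: Sequence[int], expected: Sequence[int], tol: float
) -> bool:
    """Greedy bijection of observed to expected lengths within relative tol."""
    if len(observed) != len(expected):
        return False
    remaining = sorted(expected)
    for length in sorted(observed):
        for i, e in enumerate(remaining):
            if abs(length - e) <= tol * e:
                remaining.pop(i)
                break
        else:
            return False
    return True


def call_genotype(
    fragments_observed: Iterable[int],
    assay: RflpAssay,
    tol: float = 0.02,
) -> str:
    """Diploid genotype from the observed fragment-length set.

    Only the cut pattern -> homozygous cut allele; only the uncut pattern
    -> homozygous uncut allele; the union of both -> heterozygote.  Lengths
    are matched with a relative tolerance (default 2%, gel-sizing error).
    Anything else returns ``"uninterpretable"``.
    """
    observed = sorted(set(fragments_observed))
    cut = sorted(set(assay.cut_pattern))
    uncut = sorted(set(assay.uncut_pattern))
    both = sorted(set(cut) | set(uncut))
    a, g = assay.cut_allele, assay.uncut_allele
    if _patterns_match(observed, cut, tol):
        return a + a
    if _patterns_match(observed, uncut, tol):
        return g + g
    if _patterns_match(observed, both, tol):
        return "".join(sorted(a + g))
    return "uninterpretable"


def design_rflp_assay(
    ref_allele: str,
    alt_allele: str,
    variant_position: int,
    enzyme_catalog: dict[str, RestrictionEnzyme] | None = None,
) -> list[tuple[RestrictionEnzyme, str]]:
    """Enzymes whose site count around a variant differs between alleles.

    For each catalog enzyme, occurrences overlapping the 1-based
    ``variant_position`` (a window of site-length minus one on each side)
    are counted on both alleles; a higher count on the alternate allele is
    reported as ``"created"``, a lower one as ``"destroyed"``.
    """
    if len(ref_allele) != len(alt_allele):
        raise ValueError("alleles must be equal length")
    if enzyme_catalog is None:
        enzyme_catalog = load_enzyme_catalog()
    hits = []
    for enzyme in enzyme_catalog.values():
        w = len(enzyme.recognition) - 1
        lo = max(0, variant_position - 1 - w)
        hi = min(len(ref_allele), variant_position + w)
        n_ref = len(enzyme.sites_in(ref_allele[lo:hi]))
        n_alt = len(enzyme.sites_in(alt_allele[lo:hi]))
        if n_alt > n_ref:
            hits.append((enzyme, "created"))
        elif n_alt < n_ref:
            hits.append((enzyme, "destroyed"))
    return hits
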