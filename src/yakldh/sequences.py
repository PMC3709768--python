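"""Coding-sequence handling and variant annotation.

Conventions used throughout the package:

* Nucleotide positions are 1-based on the coding sequence (CDS), with
  position 1 being the A of the initiator ATG.
* Residue positions are reported in *mature* numbering, i.e. counted after
  removal of the initiator methionine (position 1 = the residue encoded by
  codon 2).  A ``met_included`` display toggle is offered where residue
  positions are rendered, because structural work often numbers from the
  initiator Met instead.

Indels are out of scope: allele sets must be equal-length, in-frame
sequences and no alignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: residues carrying a negative side-chain charge at the neutral-pH convention
NEGATIVE_RESIDUES = frozenset("DE")
#: residues carrying a positive side-chain charge at the neutral-pH convention
POSITIVE_RESIDUES = frozenset("KRH")


class SequenceValidationError(ValueError):
    """A record violates the CodingSequence invariants."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated protein-coding DNA sequence.

    Invariants: uppercase A/C/G/T only, starts with ATG, length divisible by
    three after removing an optional trailing stop codon, and no in-frame
    internal stop codon.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        self.validate()

    def validate(self) -> None:
        bad = [i for i, b in enumerate(self.bases) if b not in _VALID_BASES]
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-ACGT character {self.bases[bad[0]]!r} "
                f"at offset {bad[0] + 1}"
            )
        if not self.bases.startswith("ATG"):
            raise SequenceValidationError(
                f"record {self.id!r}: CDS does not start with ATG"
            )
        body = self.bases
        if len(body) % 3 == 0 and body[-3:] in _STOP_CODONS:
            body = body[:-3]
        if len(body) % 3 != 0:
            raise SequenceValidationError(
                f"record {self.id!r}: length {len(self.bases)} not a whole "
                "number of codons (after removing an optional trailing stop)"
            )
        for i in range(0, len(body), 3):
            if body[i : i + 3] in _STOP_CODONS:
                raise SequenceValidationError(
                    f"record {self.id!r}: internal stop codon at codon {i // 3 + 1}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_codons(self) -> int:
        """Number of codons excluding a trailing stop."""
        body = self.bases
        if len(body) % 3 == 0 and body[-3:] in _STOP_CODONS:
            body = body[:-3]
        return len(body) // 3

    def codon(self, codon_index: int) -> str:
        """Return the codon at 1-based ``codon_index`` (Met = 1)."""
        if not 1 <= codon_index <= len(self.bases) // 3:
            raise IndexError(f"codon index {codon_index} out of range")
        return self.bases[3 * (codon_index - 1) : 3 * codon_index]

    def with_substitution(self, cds_position: int, base: str, new_id: str | None = None) -> "CodingSequence":
        """Return a copy carrying ``base`` at 1-based ``cds_position``."""
        if not 1 <= cds_position <= len(self.bases):
            raise IndexError(f"CDS position {cds_position} out of range")
        b = self.bases[: cds_position - 1] + base.upper() + self.bases[cds_position:]
        return CodingSequence(new_id or self.id, b)


@dataclass(frozen=True)
class NucleotideVariant:
    """One segregating CDS position with the base observed in each allele.

    ``states`` maps an allele label to a single base, or to an ambiguous
    pair such as ``"G/A"`` when the label denotes an allele class whose
    haplotypes differ at the site.
    """

    cds_position: int
    states: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise ValueError("CDS position must be >= 1")
        distinct = {b for s in self.states.values() for b in s.split("/")}
        if len(distinct) < 2:
            raise ValueError(
                f"variant at {self.cds_position} needs >= 2 distinct states"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(b for s in self.states.values() for b in s.split("/"))


@dataclass(frozen=True)
class CodonLocus:
    """Codon coordinates of a CDS position.

    ``mature_residue_index`` is ``None`` for codon 1 (the initiator Met has
    no mature-residue number).
    """

    codon_index: int
    codon_position: int
    mature_residue_index: int | None

    @property
    def is_initiator(self) -> bool:
        return self.mature_residue_index is None

    def residue_number(self, met_included: bool = False) -> int:
        """Residue position in the chosen numbering convention."""
        if met_included:
            return self.codon_index
        if self.mature_residue_index is None:
            raise ValueError("initiator codon has no mature residue number")
        return self.mature_residue_index


@dataclass(frozen=True)
class AminoAcidSubstitution:
    """A nonsynonymous change in mature-residue coordinates."""

    mature_residue_index: int
    ref_aa: str
    alt_aa: str
    charge_class_change: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("substitution requires ref_aa != alt_aa")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.mature_residue_index}{self.alt_aa}"


def residue_charge_class(aa: str) -> int:
    """Side-chain charge sign at the pH-7 convention: D,E -> -1; K,R,H -> +1."""
    if aa in NEGATIVE_RESIDUES:
        return -1
    if aa in POSITIVE_RESIDUES:
        return +1
    return 0


def charge_class_change(ref_aa: str, alt_aa: str) -> str:
    """Classify the charge consequence of a residue substitution.

    A sign flip (acidic to basic or vice versa) is reported as the gain of
    the new class, the dominant electrophoretic effect.
    """
    ref_c, alt_c = residue_charge_class(ref_aa), residue_charge_class(alt_aa)
    if ref_c == alt_c:
        return "none"
    if alt_c > 0:
        return "gain_positive"
    if alt_c < 0:
        return "gain_negative"
    return "lose_positive" if ref_c > 0 else "lose_negative"


def read_fasta(path: Union[str, Path], validate: bool = True) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file, preserving input order.

    With ``validate=True`` every record must satisfy the CodingSequence
    invariants; the first violation raises :class:`SequenceValidationError`
    naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if validate:
            out.append(CodingSequence(rec.id, str(rec.seq)))
        else:
            cs = object.__new__(CodingSequence)
            object.__setattr__(cs, "id", rec.id)
            object.__setattr__(cs, "bases", str(rec.seq).upper())
            out.append(cs)
    return out


def read_fasta_raw(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read any FASTA (DNA or protein) as (id, uppercase sequence) pairs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: Iterable, path: Union[str, Path]) -> None:
    """Write CodingSequence objects (or (id, string) pairs) as FASTA."""
    recs = []
    for s in sequences:
        if isinstance(s, CodingSequence):
            recs.append(SeqRecord(Seq(s.bases), id=s.id, description=""))
        else:
            sid, seq = s
            recs.append(SeqRecord(Seq(seq), id=sid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def detect_variants(sequences: Sequence[CodingSequence]) -> list[NucleotideVariant]:
    """Find every CDS position where the input alleles do not all agree.

    Requires >= 2 equal-length sequences (no alignment is attempted).
    Returns variants sorted by position, with the base of each input id
    recorded.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to detect variants")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError(
            "sequences differ in length; indels/alignment are out of scope"
        )
    variants = []
    for pos in range(1, length + 1):
        bases = {s.id: s.bases[pos - 1] for s in sequences}
        if len(set(bases.values())) > 1:
            variants.append(NucleotideVariant(pos, bases))
    return variants


def collapse_states(variant: NucleotideVariant, classes: dict[str, str]) -> NucleotideVariant:
    """Summarise per-haplotype states into per-allele-class states.

    ``classes`` maps a sequence id to its allele-class label; haplotypes of
    one class that disagree at the site are rendered as an ambiguous pair
    such as ``"G/A"`` (order of first occurrence).
    """
    per_class: dict[str, list[str]] = {}
    for sid, base in variant.states.items():
        label = classes.get(sid, sid)
        states = per_class.setdefault(label, [])
        if base not in states:
            states.append(base)
    return NucleotideVariant(
        variant.cds_position, {k: "/".join(v) for k, v in per_class.items()}
    )


def map_cds_position(cds_position: int) -> CodonLocus:
    """Map a 1-based CDS position to codon and mature-residue coordinates.

    ``codon_index = ceil(p/3)``; ``codon_position = p - 3*(codon_index-1)``;
    the mature residue index is ``codon_index - 1`` (undefined for the
    initiator codon).
    """
    if cds_position < 1:
        raise ValueError("CDS position must be >= 1")
    codon_index = ceil(cds_position / 3)
    codon_position = cds_position - 3 * (codon_index - 1)
    mature = None if codon_index == 1 else codon_index - 1
    return CodonLocus(codon_index, codon_position, mature)


def translate(cds: CodingSequence) -> str:
    """Translate with the standard genetic code; initiator Met included,
    trailing stop dropped.  An internal stop raises, naming the codon."""
    body = cds.bases
    if len(body) % 3 == 0 and body[-3:] in _STOP_CODONS:
        body = body[:-3]
    if len(body) % 3 != 0:
        raise SequenceValidationError(
            f"record {cds.id!r}: length not a whole number of codons"
        )
    protein = str(Seq(body).translate())
    star = protein.find("*")
    if star != -1:
        raise SequenceValidationError(
            f"record {cds.id!r}: internal stop codon at codon {star + 1}"
        )
    return protein


def classify_variant(
    ref: CodingSequence,
    alt: CodingSequence,
    variant: NucleotideVariant,
) -> AminoAcidSubstitution | str:
    """Classify a substitution between two alleles as synonymous or not.

    Translates the affected codon in both sequences; returns
    ``"synonymous"`` or an :class:`AminoAcidSubstitution` carrying the
    charge-class consequence.
    """
    if len(ref) != len(alt):
        raise ValueError("ref and alt must be equal length")
    locus = map_cds_position(variant.cds_position)
    ref_codon = ref.codon(locus.codon_index)
    alt_codon = alt.codon(locus.codon_index)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if locus.mature_residue_index is None:
        raise ValueError("substitution in the initiator codon is unsupported")
    return AminoAcidSubstitution(
        mature_residue_index=locus.mature_residue_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        charge_class_change=charge_class_change(ref_aa, alt_aa),
    )


def write_variant_table(
    variants: Iterable[NucleotideVariant], path: Union[str, Path]
) -> None:
    """Write a long-format variant table: position, allele label, base."""
    with open(path, "w") as fh:
        fh.write("position\tallele_label\tbase\n")
        for v in variants:
            for label, base in v.states.items():
                fh.write(f"{v.cds_position}\t{label}\t{base}\n")


def read_variant_table(path: Union[str, Path]) -> list[NucleotideVariant]:
    """Read a long-format variant table written by :func:`write_variant_table`."""
    rows: dict[int, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["position", "allele_label", "base"]:
            raise ValueError(f"{path}: unexpected variant-table header {header}")
        for line in fh:
            pos_s, label, base = line.rstrip("\n").split("\t")
            rows.setdefault(int(pos_s), {})[label] = base
    return [NucleotideVariant(p, states) for p, states in sorted(rows.items())]
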