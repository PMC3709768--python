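"""Coding-sequence handling, codon mapping and variant annotation."""

import numpy as np
import pytest

from yakldh import (
    CodingSequence,
    detect_variants,
    make_alleles,
    map_cds_position,
    read_fasta,
    translate,
    write_fasta,
    classify_variant,
)
from yakldh.sequences import (
    SequenceValidationError,
    charge_class_change,
    collapse_states,
    read_variant_table,
    write_variant_table,
)
from yakldh.synthetic_data import _SYNONYMOUS


class TestMapCdsPosition:
    @pytest.mark.parametrize(
        "cds_pos, codon_index, codon_position, mature",
        [
            (896, 299, 2, 298),   # the fast-allele Arg>Gln site
            (689, 230, 2, 229),   # the slow-allele Glu>Ala site
            (204, 68, 3, 67),     # the synonymous third-position site
            (1, 1, 1, None),
            (3, 1, 3, None),
            (4, 2, 1, 1),
        ],
    )
    def test_examples(self, cds_pos, codon_index, codon_position, mature):
        locus = map_cds_position(cds_pos)
        assert locus.codon_index == codon_index
        assert locus.codon_position == codon_position
        assert locus.mature_residue_index == mature
        assert locus.is_initiator == (mature is None)

    def test_coordinate_identity(self):
        """3*(codon_index-1) + codon_position recovers every position."""
        for p in range(1, 10001):
            locus = map_cds_position(p)
            assert 3 * (locus.codon_index - 1) + locus.codon_position == p
            assert locus.codon_position in (1, 2, 3)

    def test_numbering_toggle(self):
        locus = map_cds_position(896)
        assert locus.residue_number(met_included=False) == 298
        assert locus.residue_number(met_included=True) == 299
        with pytest.raises(ValueError):
            map_cds_position(2).residue_number()

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            map_cds_position(0)


class TestCodingSequenceValidation:
    def test_rejects_missing_start(self):
        with pytest.raises(SequenceValidationError, match="ATG"):
            CodingSequence("x", "CTGAAATAA")

    def test_rejects_non_acgt(self):
        with pytest.raises(SequenceValidationError, match="offset 4"):
            CodingSequence("x", "ATGNAATAA")

    def test_rejects_internal_stop(self):
        with pytest.raises(SequenceValidationError, match="codon 2"):
            CodingSequence("x", "ATGTAAAAATAA")

    def test_rejects_frameshift_length(self):
        with pytest.raises(SequenceValidationError, match="codons"):
            CodingSequence("x", "ATGAAAA")


class TestFastaIO:
    def test_round_trip_preserves_order_and_length(self, tmp_path, reference):
        other = reference.with_substitution(896, "A", new_id="F")
        path = tmp_path / "two.fa"
        write_fasta([reference, other], path)
        back = read_fasta(path)
        assert [s.id for s in back] == ["cattle", "F"]
        assert len(back[0]) == 1005
        assert back[0].bases == reference.bases

    def test_validation_error_names_record(self, tmp_path):
        path = tmp_path / "bad.fa"
        path.write_text(">ok\nATGGAAAAATAA\n>broken\nCCGGAAAAATAA\n")
        with pytest.raises(SequenceValidationError, match="broken"):
            read_fasta(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "absent.fa")


class TestTranslate:
    def test_standard_code(self):
        assert translate(CodingSequence("t", "ATGGAAAAATAA")) == "MEK"

    def test_full_length_cds(self, reference):
        protein = translate(reference)
        assert len(protein) == 334          # initiator Met + 333 mature residues
        assert protein[0] == "M"

    def test_round_trip_with_reverse_translation(self):
        """translate after any synonymous codon choice is the identity."""
        rng = np.random.default_rng(7)
        aas = [a for a in _SYNONYMOUS if a != "M"]
        for _ in range(25):
            protein = "M" + "".join(rng.choice(aas, size=30))
            cds = "".join(
                _SYNONYMOUS[aa][rng.integers(len(_SYNONYMOUS[aa]))] for aa in protein
            )
            # force a valid initiator codon
            cds = "ATG" + cds[3:]
            assert translate(CodingSequence("rt", cds + "TAA")) == protein


class TestDetectVariants:
    def test_identical_sequences_yield_nothing(self, reference):
        twin = CodingSequence("twin", reference.bases)
        assert detect_variants([reference, twin]) == []

    def test_single_difference_records_both_states(self, reference):
        alt = reference.with_substitution(896, "A", new_id="F")
        (v,) = detect_variants([reference, alt])
        assert v.cds_position == 896
        assert v.states == {"cattle": "G", "F": "A"}
        assert v.alleles == {"A", "G"}

    def test_unequal_lengths_rejected(self, reference):
        short = CodingSequence("s", "ATGGAAAAATAA")
        with pytest.raises(ValueError, match="length"):
            detect_variants([reference, short])

    def test_expanded_allele_set_segregates_six_positions(self, reference, config):
        expanded = make_alleles(reference, "expanded", config)
        found = detect_variants(expanded + [reference])
        assert [v.cds_position for v in found] == [53, 204, 407, 689, 700, 896]

    def test_collapse_states_renders_ambiguous_pairs(self, reference, config):
        expanded = make_alleles(reference, "expanded", config)
        found = detect_variants(expanded + [reference])
        classes = {s.id: s.id.split("_")[0] for s in expanded}
        v53 = collapse_states(found[0], classes)
        assert v53.states["F"] == "G/A"
        assert v53.states["S"] == "G"


class TestClassifyVariant:
    def test_five_nonsynonymous_one_synonymous(self, reference, config):
        """The six segregating sites annotate as five substitutions plus the
        synonymous third-position change at CDS 204."""
        expanded = make_alleles(reference, "expanded", config)
        found = detect_variants(expanded + [reference])
        results = {}
        for v in found:
            alt = next(
                s for s in expanded
                if s.bases[v.cds_position - 1] != reference.bases[v.cds_position - 1]
            )
            results[v.cds_position] = classify_variant(reference, alt, v)
        assert results[204] == "synonymous"
        nonsyn = {p: r for p, r in results.items() if r != "synonymous"}
        assert {r.mature_residue_index for r in nonsyn.values()} == {17, 135, 229, 233, 298}
        assert str(nonsyn[896]) == "R298Q"
        assert nonsyn[896].charge_class_change == "lose_positive"
        assert str(nonsyn[689]) == "E229A"
        assert nonsyn[689].charge_class_change == "lose_negative"
        assert str(nonsyn[53]) == "R17K"
        assert nonsyn[53].charge_class_change == "none"

    @pytest.mark.parametrize(
        "ref_aa, alt_aa, expected",
        [
            ("R", "Q", "lose_positive"),
            ("E", "A", "lose_negative"),
            ("A", "D", "gain_negative"),
            ("G", "K", "gain_positive"),
            ("K", "R", "none"),
            ("D", "K", "gain_positive"),  # sign flip reported as the new class
        ],
    )
    def test_charge_classes(self, ref_aa, alt_aa, expected):
        assert charge_class_change(ref_aa, alt_aa) == expected


def test_variant_table_round_trip(tmp_path, reference, config):
    expanded = make_alleles(reference, "expanded", config)
    found = detect_variants(expanded + [reference])
    path = tmp_path / "variants.tsv"
    write_variant_table(found, path)
    back = read_variant_table(path)
    assert [v.cds_position for v in back] == [v.cds_position for v in found]
    assert back[0].states == found[0].states
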