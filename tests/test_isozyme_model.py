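"""Tetramer combinatorics, band intensities, mobility and phenotype calls."""

from itertools import product

import pytest

from yakldh import (
    SubunitPool,
    band_intensities,
    classify_phenotype,
    enumerate_tetramers,
    mobility_score,
    render_pattern,
)
from yakldh.isozyme_model import (
    MERGE_THRESHOLD,
    PhasingError,
    multiset_coefficient,
)


def brute_force_compositions(n_species, isozyme_class):
    """Oracle: all slot assignments deduplicated as multisets."""
    h = 5 - isozyme_class
    return {tuple(sorted(t)) for t in product(range(n_species), repeat=h)}


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_species, isozyme_class, expected",
        [
            (2, 1, 5),   # heterozygote: five tetramer forms of the H4 isozyme
            (2, 2, 4),
            (2, 3, 3),
            (2, 4, 2),
            (2, 5, 1),
            (1, 1, 1),
            (1, 4, 1),
            (3, 1, 15),
        ],
    )
    def test_form_counts(self, n_species, isozyme_class, expected):
        comps = enumerate_tetramers(n_species, isozyme_class)
        assert len(comps) == expected
        assert len(set(comps)) == expected
        assert len(comps) == multiset_coefficient(5 - isozyme_class, n_species)

    def test_matches_brute_force_up_to_four_species(self):
        for s in range(1, 5):
            for k in range(1, 6):
                assert set(enumerate_tetramers(s, k)) == brute_force_compositions(s, k)

    def test_rejects_bad_class(self):
        with pytest.raises(ValueError):
            enumerate_tetramers(2, 0)
        with pytest.raises(ValueError):
            enumerate_tetramers(2, 6)


class TestIntensities:
    def _pool(self, canonical_profiles, m_subunit, labels, weights):
        return SubunitPool.from_profiles(
            [canonical_profiles[lab] for lab in labels], m_subunit, weights
        )

    def test_equal_expression_gives_binomial_ratios(self, canonical_profiles, m_subunit):
        pool = self._pool(canonical_profiles, m_subunit, ["Hf", "Hs"], [0.5, 0.5])
        intens = band_intensities(pool, 1)
        expected = {(0, 0, 0, 0): 1, (0, 0, 0, 1): 4, (0, 0, 1, 1): 6,
                    (0, 1, 1, 1): 4, (1, 1, 1, 1): 1}
        for comp, weight in expected.items():
            assert intens[comp] == pytest.approx(weight / 16)

    @pytest.mark.parametrize("weights", [[0.5, 0.5], [0.8, 0.2], [0.3, 0.7]])
    @pytest.mark.parametrize("isozyme_class", [1, 2, 3, 4, 5])
    def test_intensities_normalize_per_class(
        self, canonical_profiles, m_subunit, weights, isozyme_class
    ):
        pool = self._pool(canonical_profiles, m_subunit, ["Hf", "Hs"], weights)
        assert sum(band_intensities(pool, isozyme_class).values()) == pytest.approx(1.0)

    def test_degenerate_expression(self, canonical_profiles, m_subunit):
        pool = self._pool(canonical_profiles, m_subunit, ["Hf", "Hs"], [1.0, 0.0])
        intens = band_intensities(pool, 1)
        assert intens[(0, 0, 0, 0)] == pytest.approx(1.0)
        assert sum(v for c, v in intens.items() if c != (0, 0, 0, 0)) == pytest.approx(0.0)

    def test_pool_validates_weights(self, canonical_profiles, m_subunit):
        with pytest.raises(ValueError):
            self._pool(canonical_profiles, m_subunit, ["Hf", "Hs"], [0.6, 0.6])


class TestMobility:
    def test_pure_tetramer_order_is_f_m_s(self, canonical_profiles):
        scores = {
            lab: mobility_score((lab,) * 4, canonical_profiles)
            for lab in ("Hf", "Hm", "Hs")
        }
        assert scores["Hf"] > scores["Hm"] > scores["Hs"]

    def test_mixed_tetramer_scores_between_pure(self, canonical_profiles):
        hi = mobility_score(("Hf",) * 4, canonical_profiles)
        lo = mobility_score(("Hs",) * 4, canonical_profiles)
        mid = mobility_score(("Hf", "Hf", "Hs", "Hs"), canonical_profiles)
        assert lo < mid < hi

    def test_permutation_invariance(self, canonical_profiles):
        a = mobility_score(("Hf", "Hs", "Hf", "Hs"), canonical_profiles)
        b = mobility_score(("Hs", "Hs", "Hf", "Hf"), canonical_profiles)
        assert a == pytest.approx(b)

    def test_missing_profile_is_an_error(self, canonical_profiles):
        with pytest.raises(KeyError):
            mobility_score(("Hf", "Hx", "Hf", "Hf"), canonical_profiles)


class TestRenderPattern:
    def test_fs_heterozygote_resolves_into_ladders(self, canonical_profiles, m_subunit):
        """Two charge units between Hf and Hs: every class resolves fully
        (5, 4, 3, 2, 1 bands for the five isozyme classes)."""
        pool = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hs"]], m_subunit
        )
        pattern = render_pattern(pool)
        assert [len(pattern.bands_in_class(k)) for k in range(1, 6)] == [5, 4, 3, 2, 1]
        assert pattern.merge_events == ()

    def test_fm_heterozygote_collapses_to_broad_bands(self, canonical_profiles, m_subunit):
        """One charge unit between Hf and Hm: each mixed class collapses to a
        single broad band."""
        pool = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hm"]], m_subunit
        )
        pattern = render_pattern(pool)
        lanes = {k: pattern.bands_in_class(k) for k in range(1, 6)}
        for k in range(1, 5):
            assert len(lanes[k]) == 1
            assert lanes[k][0].is_broad
        assert len(lanes[5]) == 1 and not lanes[5][0].is_broad

    def test_homozygote_shows_five_classic_bands(self, canonical_profiles, m_subunit):
        pool = SubunitPool.from_profiles([canonical_profiles["Hm"]], m_subunit)
        pattern = render_pattern(pool)
        assert len(pattern.bands) == 5
        assert [b.label for b in pattern.bands] == [
            "Hm4", "Hm3M", "Hm2M2", "HmM3", "M4"
        ]

    def test_merging_conserves_intensity(self, canonical_profiles, m_subunit):
        pool = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hm"]], m_subunit
        )
        pattern = render_pattern(pool)
        for k in range(1, 6):
            total = sum(b.intensity for b in pattern.bands_in_class(k))
            assert total == pytest.approx(1.0)

    def test_bands_sorted_by_descending_mobility(self, canonical_profiles, m_subunit):
        pool = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hs"]], m_subunit
        )
        mobilities = [b.mobility for b in render_pattern(pool).bands]
        assert mobilities == sorted(mobilities, reverse=True)

    def test_threshold_extremes(self, canonical_profiles, m_subunit):
        pool = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hs"]], m_subunit
        )
        assert len(render_pattern(pool, merge_threshold=0.0).bands) == 15
        lane1 = render_pattern(pool, merge_threshold=1e6).bands_in_class(1)
        assert len(lane1) == 1 and lane1[0].is_broad

    def test_default_threshold_sits_between_the_two_regimes(
        self, canonical_profiles, m_subunit
    ):
        """The one-charge-unit spacing falls below and the two-charge-unit
        spacing above the default merge threshold."""
        fm = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hm"]], m_subunit
        )
        fs = SubunitPool.from_profiles(
            [canonical_profiles["Hf"], canonical_profiles["Hs"]], m_subunit
        )
        def class1_gaps(pool):
            bands = render_pattern(pool, merge_threshold=0.0).bands_in_class(1)
            mob = [b.mobility for b in bands]
            return [a - b for a, b in zip(mob, mob[1:])]
        assert max(class1_gaps(fm)) < MERGE_THRESHOLD
        assert min(class1_gaps(fs)) > MERGE_THRESHOLD


class TestClassifyPhenotype:
    @pytest.mark.parametrize(
        "g896, g689, expected",
        [
            ("AA", "AA", "F"),
            ("AG", "AA", "F"),   # heterozygote still shows the fast band
            ("GG", "AA", "M"),
            ("GG", "CC", "S"),
        ],
    )
    def test_unambiguous_genotypes(self, g896, g689, expected):
        assert classify_phenotype(g896, g689) == expected

    def test_fs_compound_gives_multiple_bands(self):
        assert (
            classify_phenotype("AG", "AC", haplotypes=[("A", "A"), ("G", "C")])
            == "multiple"
        )

    def test_ms_compound_reported_as_multiple(self):
        assert classify_phenotype("GG", "AC") == "multiple"

    def test_double_heterozygote_requires_phase(self):
        with pytest.raises(PhasingError):
            classify_phenotype("AG", "AC")

    def test_non_canonical_haplotype_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            classify_phenotype("AA", "CC")

    def test_inconsistent_haplotypes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            classify_phenotype("AG", "AA", haplotypes=[("A", "A"), ("A", "A")])
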