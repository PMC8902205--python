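import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from candgene.errors import MonomorphicLocusError, UndefinedStatisticError
from candgene.popgen import (
    allele_frequencies,
    diversity_indices,
    hwe_chi2_test,
    hwe_expected_counts,
    summarize_loci,
)

from ._oracles import allele_freqs_by_enumeration, hwe_chi2_recompute
from .conftest import TABLE3


class TestAlleleFrequencies:
    def test_published_genotype_frequencies_give_printed_allele_frequencies(self):
        # inputs are rounded to 2 d.p., so recomputed values can sit half a
        # rounding unit away from the printed ones
        for locus, (gfreq, afreq, *_rest) in TABLE3.items():
            p_ref, p_alt = allele_frequencies(gfreq)
            assert p_ref == pytest.approx(afreq[0], abs=0.0051), locus
            assert p_alt == pytest.approx(afreq[1], abs=0.0051), locus

    def test_fixed_locus(self):
        assert allele_frequencies((25, 0, 0)) == (1.0, 0.0)

    def test_all_missing_is_an_error(self):
        with pytest.raises(UndefinedStatisticError):
            allele_frequencies((0, 0, 0))

    def test_matches_brute_force_allele_enumeration(self, rng):
        for _ in range(50):
            n_rr, n_het, n_aa = rng.integers(0, 60, size=3)
            if n_rr + n_het + n_aa == 0:
                continue
            calls = ["CC"] * n_rr + ["CA"] * n_het + ["AA"] * n_aa
            expected = allele_freqs_by_enumeration(calls)
            p_ref, p_alt = allele_frequencies((n_rr, n_het, n_aa))
            assert p_ref == pytest.approx(expected.get("C", 0.0), abs=1e-12)
            assert p_alt == pytest.approx(expected.get("A", 0.0), abs=1e-12)


class TestDiversityIndices:
    @pytest.mark.parametrize("locus", ["g.5070C>A", "g.5076T>C", "g.5148A>C"])
    def test_printed_allele_frequencies_reproduce_printed_indices(self, locus):
        # the published table was computed before rounding its own allele
        # frequencies; for these loci the 2-d.p. frequencies round-trip the
        # printed indices (the other two loci rounded too coarsely for that)
        _, afreq, _, _, ho, he, ne, pic = TABLE3[locus]
        d = diversity_indices(afreq)
        assert d.ho == pytest.approx(ho, abs=0.005)
        assert d.he == pytest.approx(he, abs=0.005)
        assert d.ne == pytest.approx(ne, abs=0.005)
        assert d.pic == pytest.approx(pic, abs=0.005)

    @pytest.mark.parametrize("locus", sorted(TABLE3))
    def test_printed_rows_are_internally_consistent(self, locus):
        # whatever the unrounded inputs were, He = 1 - Ho and Ne = 1/Ho must
        # hold among the printed values to print precision
        _, _, _, _, ho, he, ne, _ = TABLE3[locus]
        assert ho + he == pytest.approx(1.0, abs=0.001)
        assert ne == pytest.approx(1.0 / ho, abs=0.005)

    def test_symmetric_biallelic_maximum(self):
        d = diversity_indices((0.5, 0.5))
        assert (d.he, d.ne, d.pic) == (0.5, 2.0, 0.375)

    def test_monomorphic_locus(self):
        d = diversity_indices((1.0, 0.0))
        assert (d.ho, d.he, d.ne, d.pic) == (1.0, 0.0, 1.0, 0.0)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_biallelic_identities(self, p):
        d = diversity_indices((p, 1 - p))
        assert d.ho + d.he == pytest.approx(1.0, abs=1e-12)
        assert d.ne * d.ho == pytest.approx(1.0, abs=1e-12)
        # biallelic closed form PIC = He - 2 p^2 q^2
        assert d.pic == pytest.approx(d.he - 2 * p**2 * (1 - p) ** 2, abs=1e-12)

    @given(st.lists(st.floats(min_value=1e-3, max_value=1.0), min_size=2, max_size=6))
    def test_pic_never_exceeds_gene_diversity(self, raw):
        p = np.array(raw) / np.sum(raw)
        d = diversity_indices(p)
        assert d.pic <= d.he + 1e-12
        if np.max(p) < 1.0 - 1e-9:
            assert d.pic < d.he


class TestHweChi2:
    def test_exact_hwe_counts_give_zero_statistic(self):
        chi2, df, p = hwe_chi2_test((25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # counts (50, 30, 20): p_ref = 0.65, expected (42.25, 45.5, 12.25)
        exp = hwe_expected_counts((50, 30, 20))
        assert exp == pytest.approx([42.25, 45.5, 12.25])
        chi2, df, _ = hwe_chi2_test((50, 30, 20))
        assert chi2 == pytest.approx(11.6049, abs=1e-4)
        assert df == 2

    def test_df_modes(self):
        chi2_leg, df_leg, p_leg = hwe_chi2_test((50, 30, 20), df_mode="legacy")
        chi2_std, df_std, p_std = hwe_chi2_test((50, 30, 20), df_mode="standard")
        assert chi2_leg == chi2_std
        assert (df_leg, df_std) == (2, 1)
        assert p_std < p_leg  # same statistic, thinner tail at 1 df

    def test_monotone_in_heterozygote_deficit(self):
        # fix allele counts (p = 0.5), shrink the het class step by step
        stats = []
        for n_het in range(50, 8, -2):
            n_hom = (100 - n_het) // 2
            stats.append(hwe_chi2_test((n_hom, n_het, n_hom))[0])
        assert all(b > a for a, b in zip(stats, stats[1:]))

    def test_monomorphic_is_an_error(self):
        with pytest.raises(MonomorphicLocusError):
            hwe_chi2_test((30, 0, 0))


class TestSummarizeLoci:
    def test_five_locus_summary_shape_and_invariants(self, default_genotypes):
        rows = summarize_loci(default_genotypes)
        assert len(rows) == 5
        for r in rows:
            assert r.ho + r.he == pytest.approx(1.0, abs=1e-12)
            assert r.ne * r.ho == pytest.approx(1.0, abs=1e-12)
            assert sum(r.genotype_freqs) == pytest.approx(1.0, abs=1e-9)
            assert sum(r.allele_freqs) == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= r.pic <= r.he <= 1.0
            assert all(c > 0 for c in r.genotype_counts)  # all 3 genotypes segregate

    def test_indices_agree_with_composition_of_primitives(self, default_genotypes):
        for r in summarize_loci(default_genotypes):
            counts = default_genotypes.genotype_counts(r.locus_id)
            freqs = allele_frequencies(counts)
            d = diversity_indices(freqs)
            assert (r.ho, r.he, r.ne, r.pic) == (d.ho, d.he, d.ne, d.pic)
            assert r.chi2 == pytest.approx(hwe_chi2_recompute(counts), abs=1e-10)

    def test_failed_locus_is_flagged_not_fatal(self):
        from candgene.io import GenotypeMatrix, SnpDef

        panel = [SnpDef("g.244C>G", "C", "G"), SnpDef("g.400G>A", "G", "A")]
        gm = GenotypeMatrix.from_calls(
            ["a", "b"], panel, {"g.244C>G": ["CC", "CC"], "g.400G>A": ["GA", "AA"]}
        )
        rows = summarize_loci(gm)
        assert rows[0].error is not None  # monomorphic: HWE undefined
        assert rows[1].error is None
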