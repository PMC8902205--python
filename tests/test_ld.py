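import math

import numpy as np
import pytest

from candgene.errors import MonomorphicLocusError, UndefinedStatisticError
from candgene.io import GenotypeMatrix, SnpDef
from candgene.ld import (
    LdPair,
    _compatible_pairs,
    assign_diplotypes,
    em_haplotype_frequencies,
    filter_haplotypes,
    ld_from_haplotypes,
    ld_matrix,
    ld_summary,
)
from candgene.synthpop import SimConfig, generate_population

from ._oracles import compatible_pairs_brute, max_likelihood_haplotypes
from .conftest import TABLE4, TABLE5

PANEL2 = [SnpDef("locA", "A", "G"), SnpDef("locB", "T", "C")]
PANEL3 = PANEL2 + [SnpDef("locC", "C", "G")]


def _matrix(panel, rows):
    ids = [f"i{k}" for k in range(len(rows))]
    cols = {s.locus_id: [r[j] for r in rows] for j, s in enumerate(panel)}
    return GenotypeMatrix.from_calls(ids, panel, cols)


class TestPhaseEnumeration:
    @pytest.mark.parametrize(
        "calls",
        [["AA", "TT"], ["AG", "TT"], ["AG", "TC"], ["AG", "TC", "CG"], ["AA", "TC", "CG"]],
    )
    def test_matches_brute_force_enumeration(self, calls):
        assert sorted(_compatible_pairs(calls)) == compatible_pairs_brute(calls)

    def test_pair_count_is_two_to_the_hets_minus_one(self):
        calls = ["AG", "TC", "CG"]
        assert len(_compatible_pairs(calls)) == 4


class TestEmHaplotypes:
    def test_unambiguous_phase_equals_direct_gene_counting(self):
        # at most one heterozygous locus per animal: no phase ambiguity
        rows = [["AA", "TT"], ["AA", "TC"], ["AG", "CC"], ["GG", "CC"], ["AA", "TT"]]
        gm = _matrix(PANEL2, rows)
        hs = em_haplotype_frequencies(gm, seed=0)
        # count gametes directly: AT x5, AC x2, GC x3 out of 10
        expected = {"AT": 0.5, "AC": 0.2, "GC": 0.3}
        for hap, freq in expected.items():
            assert hs.frequency(hap) == pytest.approx(freq, abs=1e-9)

    def test_coupling_fixed_point_from_mostly_homozygous_data(self):
        # 4 AABB + 4 aabb + 2 AaBb converges to 0.5/0.5 coupling haplotypes
        rows = [["AA", "TT"]] * 4 + [["GG", "CC"]] * 4 + [["AG", "TC"]] * 2
        hs = em_haplotype_frequencies(_matrix(PANEL2, rows), seed=0)
        assert hs.converged
        assert hs.frequency("AT") == pytest.approx(0.5, abs=1e-6)
        assert hs.frequency("GC") == pytest.approx(0.5, abs=1e-6)
        assert hs.frequency("AC") == pytest.approx(0.0, abs=1e-6)
        assert hs.frequency("GT") == pytest.approx(0.0, abs=1e-6)

    def test_loglik_is_nondecreasing_every_iteration(self, default_genotypes):
        hs = em_haplotype_frequencies(default_genotypes, seed=3, n_restarts=2)
        diffs = np.diff(hs.loglik_history)
        assert np.all(diffs >= -1e-9)

    def test_frequencies_form_a_distribution(self, default_genotypes):
        hs = em_haplotype_frequencies(default_genotypes, seed=3)
        assert np.all(hs.freqs >= 0)
        assert hs.freqs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_no_complete_cases_is_an_error(self):
        gm = _matrix(PANEL2, [["NN", "TT"], ["AA", "NN"]])
        with pytest.raises(UndefinedStatisticError):
            em_haplotype_frequencies(gm)

    @pytest.mark.parametrize("case", ["two_locus_mixed", "three_locus", "no_double_het"])
    def test_em_matches_brute_force_simplex_maximizer(self, case):
        if case == "two_locus_mixed":
            rows = [["AA", "TT"]] * 3 + [["GG", "CC"]] * 3 + [["AG", "TC"]] * 4 + [["AG", "TT"]] * 2
            panel = PANEL2
        elif case == "three_locus":
            cfg = SimConfig(
                n_individuals=12,
                panel=tuple(PANEL3),
                hap_pool={"ATC": 0.4, "GCG": 0.3, "ATG": 0.2, "GCC": 0.1},
                seed=11,
            )
            gm, _ = generate_population(cfg)
            rows = gm.calls.values.tolist()
            panel = PANEL3
        else:
            rows = [["AA", "TC"], ["AG", "TT"], ["AG", "CC"], ["GG", "TC"], ["AA", "TT"]]
            panel = PANEL2
        gm = _matrix(panel, rows)
        hs = em_haplotype_frequencies(gm, seed=0, n_restarts=8)
        oracle = max_likelihood_haplotypes(gm.calls.values.tolist(), seed=1)
        for hap in set(hs.haplotypes) | set(oracle):
            assert hs.frequency(hap) == pytest.approx(oracle.get(hap, 0.0), abs=1e-4), hap


class TestLdFromHaplotypes:
    def test_closed_form_hand_computation(self):
        pair = ld_from_haplotypes((0.4, 0.1, 0.1, 0.4))
        assert pair.d == pytest.approx(0.15)
        assert pair.d_prime == pytest.approx(0.6)
        assert pair.r2 == pytest.approx(0.36)

    def test_complete_coupling(self):
        pair = ld_from_haplotypes((0.5, 0.0, 0.0, 0.5))
        assert pair.d == pytest.approx(0.25)
        assert pair.d_prime == pytest.approx(1.0)
        assert pair.r2 == pytest.approx(1.0)

    def test_linkage_equilibrium(self):
        p_a, p_b = 0.3, 0.6
        f = (p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b))
        pair = ld_from_haplotypes(f)
        assert pair.d == pytest.approx(0.0, abs=1e-15)
        assert pair.d_prime == 0.0
        assert pair.r2 == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_locus_is_an_error(self):
        with pytest.raises(MonomorphicLocusError):
            ld_from_haplotypes((0.7, 0.3, 0.0, 0.0))

    def test_invariant_to_allele_relabeling(self, rng):
        for _ in range(25):
            f = rng.dirichlet(np.ones(4))
            base = ld_from_haplotypes(tuple(f))
            # swap ref/alt at locus A: (AB,Ab,aB,ab) -> (aB,ab,AB,Ab)
            swapped_a = ld_from_haplotypes((f[2], f[3], f[0], f[1]))
            # swap at locus B
            swapped_b = ld_from_haplotypes((f[1], f[0], f[3], f[2]))
            for other in (swapped_a, swapped_b):
                assert other.d_prime == pytest.approx(base.d_prime, abs=1e-12)
                assert other.r2 == pytest.approx(base.r2, abs=1e-12)


class TestLdMatrix:
    def test_published_r2_values_summarize_to_printed_mean(self):
        pairs = [
            LdPair(a, b, float("nan"), dp, r2) for (a, b), (dp, r2) in TABLE4.items()
        ]
        summary = ld_summary(pairs)
        assert summary.mean_r2 == pytest.approx(0.329, abs=1e-12)
        assert summary.strong_pairs == [
            ("g.5070C>A", "g.5076T>C"),
            ("g.5070C>A", "g.5148A>C"),
            ("g.5076T>C", "g.5148A>C"),
        ]

    def test_two_locus_matrix_mean_equals_single_pair(self):
        rows = [["AA", "TT"]] * 4 + [["GG", "CC"]] * 4 + [["AG", "TC"]] * 2
        res = ld_matrix(_matrix(PANEL2, rows))
        assert len(res.pairs) == 1
        assert res.mean_r2 == res.pairs[0].r2
        assert res.mean_d_prime == res.pairs[0].d_prime

    def test_simulated_herd_reproduces_strong_and_weak_ld_contrast(self, default_genotypes):
        res = ld_matrix(default_genotypes, seed=0)
        assert len(res.pairs) == 10
        by_pair = {(p.locus_a, p.locus_b): p for p in res.pairs}
        for pair in [("g.5070C>A", "g.5076T>C"), ("g.5070C>A", "g.5148A>C"),
                     ("g.5076T>C", "g.5148A>C")]:
            assert by_pair[pair].r2 > 0.33
        assert by_pair[("g.400G>A", "g.5070C>A")].r2 < 0.1

    def test_monomorphic_locus_flagged_not_fatal(self):
        panel = PANEL2 + [SnpDef("locM", "A", "C")]
        rows = [["AA", "TT", "AA"], ["GG", "CC", "AA"], ["AG", "TC", "AA"],
                ["AA", "TC", "AA"]]
        res = ld_matrix(_matrix(panel, rows))
        assert len(res.pairs) == 1  # only locA-locB is defined
        assert len(res.errors) == 2


class TestFilterHaplotypes:
    def test_study_frequency_profile_retains_five(self):
        freqs = list(TABLE5.values()) + [0.102 / 7] * 7
        haps = list(TABLE5) + [f"X{i}" for i in range(7)]
        import numpy as np

        from candgene.ld import HaplotypeSet

        hs = HaplotypeSet(loci=["a"], haplotypes=haps, freqs=np.array(freqs),
                          loglik=0.0, n_iter=1, converged=True)
        kept = filter_haplotypes(hs, 0.05)
        assert kept.haplotypes == list(TABLE5)
        assert kept.n_discarded == 7
        assert kept.freqs.sum() == pytest.approx(0.898, abs=1e-9)
        assert kept.freqs.sum() + kept.discarded_mass == pytest.approx(1.0, abs=1e-8)

    def test_zero_threshold_is_identity(self, default_genotypes):
        hs = em_haplotype_frequencies(default_genotypes, seed=0)
        kept = filter_haplotypes(hs, 0.0)
        assert kept.haplotypes == hs.haplotypes
        assert kept.n_discarded == 0


class TestAssignDiplotypes:
    def test_fully_homozygous_individual_has_posterior_one(self):
        rows = [["AA", "TT"], ["GG", "CC"], ["AG", "TC"]]
        gm = _matrix(PANEL2, rows)
        hs = em_haplotype_frequencies(gm, seed=0)
        assigns, _, _ = assign_diplotypes(gm, hs)
        assert assigns[0].hap_pair == ("AT", "AT")
        assert assigns[0].posterior == pytest.approx(1.0)

    def test_tie_break_is_deterministic_lexicographic(self):
        # symmetric double het: both phase pairs equally likely
        rows = [["AG", "TC"]] * 6
        gm = _matrix(PANEL2, rows)
        hs = em_haplotype_frequencies(gm, seed=0, n_restarts=1)
        first = [assign_diplotypes(gm, hs)[0][0].hap_pair for _ in range(3)]
        assert len(set(first)) == 1
        assert first[0] == min(first[0], tuple(sorted(("AC", "GT"))))

    def test_incompatible_with_retained_set_falls_back_flagged(self):
        rows = [["AA", "TT"]] * 10 + [["GG", "CC"]]
        gm = _matrix(PANEL2, rows)
        hs = em_haplotype_frequencies(gm, seed=0)
        kept = filter_haplotypes(hs, 0.05)
        assert "GC" not in kept.haplotypes or kept.frequency("GC") < 0.1
        assigns, _, _ = assign_diplotypes(gm, filter_haplotypes(hs, 0.2), full_hapset=hs)
        rare = assigns[-1]
        assert rare.hap_pair == ("GC", "GC")
        assert rare.flagged

    def test_expected_common_classes_appear_in_simulated_herd(self, default_dataset):
        ds, _ = default_dataset
        gm = ds.genotypes
        hs = em_haplotype_frequencies(gm, seed=0)
        assigns, class_freqs, retained = assign_diplotypes(gm, filter_haplotypes(hs, 0.05),
                                                           full_hapset=hs)
        # the five most frequent diplotype classes of the study design:
        # H1H2, H1H3, H2H2, H3H3, H1H1 written as per-locus genotype strings
        def class_of(h1, h2):
            return "".join(
                a + b if a == b else ref + alt
                for a, b, (ref, alt) in zip(
                    h1, h2, [(s.allele_ref, s.allele_alt) for s in gm.panel]
                )
            )

        expected = {
            class_of("CACTA", "GAACC"), class_of("CACTA", "GGCTA"),
            class_of("GAACC", "GAACC"), class_of("GGCTA", "GGCTA"),
            class_of("CACTA", "CACTA"),
        }
        top = sorted(class_freqs, key=class_freqs.get, reverse=True)[:6]
        assert expected <= set(top)
        assert expected <= set(retained)
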