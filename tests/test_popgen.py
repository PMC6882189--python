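"""Diversity indices, Phi_ST, Nm, AMOVA and chi-squared cohort tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from equihap.popgen import (
    PopulationSample,
    amova,
    chi2_cohort_test,
    haplotype_diversity,
    nm_from_phist,
    nucleotide_diversity,
    pairwise_phist,
)

from _oracles import pearson_chi2_bruteforce
from conftest import make_profile, random_label_profiles


def pop(name, label_sets):
    return PopulationSample(name, [make_profile(f"{name}{i}", labels)
                                   for i, labels in enumerate(label_sets)])


class TestDiversity:
    def test_monomorphic_population_has_zero_diversity(self):
        p = pop("A", [["15500"]] * 4)
        assert haplotype_diversity(p) == 0.0
        assert nucleotide_diversity(p, 247) == 0.0

    def test_two_distinct_sequences_give_h_one(self):
        assert haplotype_diversity(pop("A", [[], ["15500"]])) == pytest.approx(1.0)

    def test_counts_2_1_1_match_nei_formula(self):
        p = pop("A", [["15500"], ["15500"], ["15505"], ["15510"]])
        assert haplotype_diversity(p) == pytest.approx(5 / 6)  # (4/3)(1 - 0.375)

    def test_single_site_pair_nucleotide_diversity(self):
        p = pop("A", [[], ["15500"]])
        assert nucleotide_diversity(p, 247) == pytest.approx(1 / 247)

    def test_nucleotide_diversity_permutation_invariant(self):
        rng = np.random.default_rng(4)
        profiles = random_label_profiles(rng, 6)
        a = PopulationSample("A", profiles)
        b = PopulationSample("A", profiles[::-1])
        assert nucleotide_diversity(a, 247) == nucleotide_diversity(b, 247)

    def test_singleton_population_rejected(self):
        p = pop("A", [["15500"]])
        with pytest.raises(ValueError):
            haplotype_diversity(p)
        with pytest.raises(ValueError):
            nucleotide_diversity(p, 247)


class TestPairwisePhist:
    def test_identical_monomorphic_populations_have_zero_phist(self):
        sets = [["15500"]] * 3
        assert pairwise_phist(pop("A", sets), pop("B", sets)) == pytest.approx(0.0, abs=1e-9)

    def test_identical_polymorphic_populations_show_no_differentiation(self):
        # the unbiased among-population component is non-positive when the
        # two samples are exact copies; it is reported as computed
        sets = [[], ["15500"], ["15505"]]
        assert pairwise_phist(pop("A", sets), pop("B", sets)) <= 0.0

    def test_fixed_difference_gives_phist_one(self):
        a = pop("A", [["15500"]] * 3)
        b = pop("B", [["15505"]] * 3)
        assert pairwise_phist(a, b) == pytest.approx(1.0)

    def test_hand_computed_three_plus_three_instance(self):
        # hand-executed sums of squares: SSD_T=19/6, SSD_WP=4/3,
        # sigma_a=0.5, sigma_w=1/3, Phi_ST=0.6
        a = pop("A", [[], [], ["15500"]])
        b = pop("B", [["15600C"], ["15600C"], ["15600C", "15700"]])
        assert pairwise_phist(a, b) == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a = PopulationSample("A", random_label_profiles(rng, 5))
        b = PopulationSample("B", random_label_profiles(rng, 7))
        assert pairwise_phist(a, b) == pytest.approx(pairwise_phist(b, a))

    def test_singleton_population_rejected(self):
        with pytest.raises(ValueError):
            pairwise_phist(pop("A", [[]]), pop("B", [[], ["15500"]]))


class TestNm:
    def test_phi_point_two_gives_two_migrants(self):
        assert nm_from_phist(0.2) == pytest.approx(2.0)

    def test_undifferentiated_populations_give_infinite_flow(self):
        assert math.isinf(nm_from_phist(0.0))
        assert math.isinf(nm_from_phist(-0.05))

    def test_complete_differentiation_gives_zero_flow(self):
        assert nm_from_phist(1.0) == 0.0

    def test_phist_above_one_rejected(self):
        with pytest.raises(ValueError):
            nm_from_phist(1.2)

    @given(st.floats(0.01, 0.99))
    def test_island_model_round_trip(self, phi):
        nm = nm_from_phist(phi)
        assert 1.0 / (2.0 * nm + 1.0) == pytest.approx(phi)


class TestAMOVA:
    def _null_populations(self, rng, n_pops=6, n_ind=5):
        pops = [PopulationSample(f"P{i}", random_label_profiles(
            rng, n_ind, n_sites=15, p=0.2)) for i in range(n_pops)]
        groups = {f"P{i}": ("G1" if i < n_pops // 2 else "G2") for i in range(n_pops)}
        return pops, groups

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        pops, groups = self._null_populations(rng)
        res = amova(pops, groups, n_permutations=99, seed=3)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(res.display_percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_null_data_has_negligible_among_group_component(self):
        rng = np.random.default_rng(2)
        pcts = []
        for _ in range(20):
            pops, groups = self._null_populations(rng)
            res = amova(pops, groups, n_permutations=99, seed=0, components=())
            pcts.append(res.percentages["among_groups"])
        assert abs(np.mean(pcts)) < 5.0

    def test_null_p_values_are_not_degenerate(self):
        rng = np.random.default_rng(3)
        ps = []
        for i in range(40):
            pops, groups = self._null_populations(rng)
            res = amova(pops, groups, n_permutations=99, seed=i, components=("CT",))
            ps.append(res.p_values["among_groups"])
        assert 0.25 < np.mean(ps) < 0.75

    def test_fixed_group_difference_gives_all_among_group_variance(self):
        pops = [
            pop("A1", [["15500"]] * 4), pop("A2", [["15500"]] * 4),
            pop("B1", [["15600C", "15700"]] * 4), pop("B2", [["15600C", "15700"]] * 4),
        ]
        groups = {"A1": "G1", "A2": "G1", "B1": "G2", "B2": "G2"}
        res = amova(pops, groups, n_permutations=99, seed=0, components=("CT",))
        assert res.percentages["among_groups"] == pytest.approx(100.0)
        assert res.phi_statistics["phi_ct"] == pytest.approx(1.0)

    def test_among_group_share_grows_with_planted_divergence(self):
        rng = np.random.default_rng(9)
        shares = []
        for extra in (0, 2, 5, 10):
            group_b_private = [str(15800 + i) for i in range(extra)]
            pops = []
            for g, private in (("A", []), ("B", group_b_private)):
                for k in range(2):
                    profiles = []
                    for i in range(6):
                        noise = [str(15500 + s) for s in range(12) if rng.random() < 0.2]
                        profiles.append(make_profile(f"{g}{k}s{i}",
                                                     sorted(set(noise) | set(private))))
                    pops.append(PopulationSample(f"{g}{k}", profiles))
            groups = {"A0": "GA", "A1": "GA", "B0": "GB", "B1": "GB"}
            res = amova(pops, groups, n_permutations=99, seed=1, components=())
            shares.append(res.percentages["among_groups"])
        assert shares == sorted(shares)

    def test_haplotype_incidence_metric_binarizes_distances(self):
        # with every pair either identical or distinct, both metrics agree
        pops = [pop("A1", [["15500"]] * 3), pop("A2", [["15500"]] * 3),
                pop("B1", [["15505"]] * 3), pop("B2", [["15505"]] * 3)]
        groups = {"A1": "G1", "A2": "G1", "B1": "G2", "B2": "G2"}
        by_diff = amova(pops, groups, n_permutations=99, seed=0, components=())
        by_inc = amova(pops, groups, n_permutations=99, seed=0, components=(),
                       metric="haplotype_incidence")
        assert by_inc.phi_statistics == by_diff.phi_statistics
        # scaling one distance no longer matters under incidence
        pops2 = [pop("A1", [["15500"]] * 3), pop("A2", [["15500"]] * 3),
                 pop("B1", [["15505", "15510", "15515"]] * 3),
                 pop("B2", [["15505", "15510", "15515"]] * 3)]
        by_inc2 = amova(pops2, groups, n_permutations=99, seed=0, components=(),
                        metric="haplotype_incidence")
        assert by_inc2.phi_statistics["phi_ct"] == pytest.approx(
            by_inc.phi_statistics["phi_ct"])

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(0)
        pops, groups = self._null_populations(rng)
        with pytest.raises(ValueError):
            amova(pops, groups, n_permutations=50)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(0)
        pops, _ = self._null_populations(rng)
        with pytest.raises(ValueError):
            amova(pops, {p.population: "G1" for p in pops}, n_permutations=99)


class TestChi2CohortTest:
    def test_identical_proportions_give_zero_statistic(self):
        res = chi2_cohort_test((10, 20), (50, 100))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_two_by_two_table(self):
        # E = [[20,80],[20,80]]; chi2 = 5 + 1.25 + 5 + 1.25 = 12.5
        res = chi2_cohort_test((10, 30), (100, 100))
        assert res.statistic == pytest.approx(12.5)
        assert res.df == 1
        assert res.p_value == pytest.approx(4.0695e-4, rel=1e-3)

    def test_swapping_cohorts_preserves_statistic(self):
        a = chi2_cohort_test((7, 19), (40, 60))
        b = chi2_cohort_test((19, 7), (60, 40))
        assert a.statistic == pytest.approx(b.statistic)

    def test_absent_haplogroup_reports_null_result(self):
        res = chi2_cohort_test((0, 0), (30, 40))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_low_expected_cell_flagged_not_suppressed(self):
        res = chi2_cohort_test((1, 0), (3, 3))
        assert res.low_expected
        assert res.statistic >= 0.0

    def test_count_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError):
            chi2_cohort_test((10, 5), (8, 20))

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(20, 80), st.integers(20, 80))
    def test_matches_bruteforce_pearson(self, k1, k2, extra1, extra2):
        n1, n2 = k1 + extra1, k2 + extra2
        res = chi2_cohort_test((k1, k2), (n1, n2))
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        assert res.statistic == pytest.approx(pearson_chi2_bruteforce(table))
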