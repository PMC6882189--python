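"""Motif inference and (near-)matching haplogroup assignment."""

import numpy as np
import pytest

from equihap.motifs import (
    NOMENCLATURE_MERGES,
    UNCLASSIFIED,
    Motif,
    assign_haplogroup,
    classify_dataset,
    infer_motifs,
)
from equihap.simulate import HaplogroupSpec, PopulationSpec, SimulationConfig, simulate_samples
from equihap.window import HaplotypeProfile

from conftest import make_profile


def motif(hg, labels, support=2):
    return Motif(hg, frozenset(labels), support)


class TestInferMotifs:
    def test_disjoint_private_variants_become_motifs(self):
        labelled = [
            (make_profile("a1", ["15500"]), "A"),
            (make_profile("a2", ["15500"]), "A"),
            (make_profile("b1", ["15602C"]), "B"),
        ]
        motifs = {m.haplogroup: m.diagnostic_variants for m in infer_motifs(labelled)}
        assert motifs == {"A": {"15500"}, "B": {"15602C"}}

    def test_shared_variant_excluded_from_both(self):
        labelled = [
            (make_profile("a1", ["15500", "15510"]), "A"),
            (make_profile("b1", ["15500", "15602C"]), "B"),
        ]
        motifs = {m.haplogroup: m.diagnostic_variants for m in infer_motifs(labelled)}
        assert motifs == {"A": {"15510"}, "B": {"15602C"}}

    def test_window_restriction_can_empty_a_motif(self, small_window, caplog):
        # one group's private variants all lie outside the analysed window,
        # mirroring backbone haplogroups with no motif in the short fragment
        labelled = [
            (make_profile("a1", ["15800"]), "A"),   # outside 15494-15513
            (make_profile("b1", ["15500"]), "B"),
        ]
        with caplog.at_level("WARNING"):
            motifs = {m.haplogroup: m.diagnostic_variants
                      for m in infer_motifs(labelled, window=small_window)}
        assert motifs["A"] == frozenset()
        assert motifs["B"] == {"15500"}
        assert any("no diagnostic motif" in r.message for r in caplog.records)

    def test_member_missing_at_position_does_not_veto(self):
        labelled = [
            (make_profile("a1", ["15500", "15505"]), "A"),
            (make_profile("a2", ["15500"], missing=[15505]), "A"),
            (make_profile("b1", ["15602C"]), "B"),
        ]
        motifs = {m.haplogroup: m.diagnostic_variants for m in infer_motifs(labelled)}
        assert motifs["A"] == {"15500", "15505"}

    def test_single_label_raises(self):
        with pytest.raises(ValueError):
            infer_motifs([(make_profile("a1", ["15500"]), "A")])

    def test_rename_map_merges_nomenclature(self):
        labelled = [
            (make_profile("j1", ["15500"]), "J"),
            (make_profile("k1", ["15500"]), "K"),
            (make_profile("d1", ["15602C"]), "D"),
        ]
        motifs = {m.haplogroup: m for m in
                  infer_motifs(labelled, rename_map=NOMENCLATURE_MERGES)}
        assert set(motifs) == {"KJ", "D"}
        assert motifs["KJ"].diagnostic_variants == {"15500"}
        assert motifs["KJ"].training_support == 2

    def test_exclusivity_holds_on_random_training_sets(self):
        rng = np.random.default_rng(3)
        labelled = []
        for g in range(4):
            for i in range(5):
                labels = {str(15500 + int(s)) for s in rng.integers(0, 40, size=6)}
                labelled.append((make_profile(f"g{g}i{i}", sorted(labels)), f"G{g}"))
        motifs = infer_motifs(labelled)
        for i, m in enumerate(motifs):
            for other in motifs[i + 1:]:
                assert m.diagnostic_variants.isdisjoint(other.diagnostic_variants)


class TestAssignHaplogroup:
    MOTIFS = [motif("Q", ["15500", "15505", "15510"]), motif("R", ["15601", "15602"])]

    def test_exact_superset_match(self):
        call = assign_haplogroup(make_profile("s", ["15500", "15505", "15510", "15520"]),
                                 self.MOTIFS)
        assert (call.haplogroup, call.mode, call.matched_fraction) == ("Q", "exact_motif", 1.0)

    def test_near_match_two_of_three(self):
        call = assign_haplogroup(make_profile("s", ["15500", "15505"]), self.MOTIFS,
                                 min_fraction=0.5)
        assert call.haplogroup == "Q" and call.mode == "near_match"
        assert call.matched_fraction == pytest.approx(2 / 3)

    def test_no_motif_variant_is_unclassified(self):
        call = assign_haplogroup(make_profile("s", ["15999"]), self.MOTIFS)
        assert call.haplogroup == UNCLASSIFIED and call.mode == "unclassified"

    def test_below_fraction_threshold_unclassified(self):
        call = assign_haplogroup(make_profile("s", ["15500"]), self.MOTIFS,
                                 min_fraction=0.5)
        assert call.haplogroup == UNCLASSIFIED
        assert call.matched_fraction == pytest.approx(1 / 3)

    def test_missing_motif_sites_excluded_from_denominator(self):
        # two of Q's three sites unreadable; the remaining one matches
        call = assign_haplogroup(
            make_profile("s", ["15510"], missing=[15500, 15505]), self.MOTIFS)
        assert call.haplogroup == "Q" and call.matched_fraction == 1.0

    def test_exact_tie_between_haplogroups_flags_conflict(self, caplog):
        motifs = [motif("A", ["15500"]), motif("B", ["15505"])]
        with caplog.at_level("WARNING"):
            call = assign_haplogroup(make_profile("s", ["15500", "15505"]), motifs)
        assert call.haplogroup == UNCLASSIFIED
        assert any("conflict" in r.message for r in caplog.records)

    def test_empty_motif_never_assigned(self):
        motifs = [motif("A", []), motif("B", ["15505"])]
        call = assign_haplogroup(make_profile("s", ["15500"]), motifs)
        assert call.haplogroup == UNCLASSIFIED

    def test_all_empty_motifs_raise(self):
        with pytest.raises(ValueError):
            assign_haplogroup(make_profile("s", ["15500"]), [motif("A", [])])


def _planted_config(seed, n_per_hg=20, dropout=0.0, rate=0.0):
    """One single-haplogroup population per haplogroup: exact planted counts."""
    names = ["Q", "R"]
    hgs = [HaplogroupSpec(n, motif_size=3, mutation_rate=rate) for n in names]
    pops = [PopulationSpec(f"P{n}", "NEA", n_per_hg, {n: 1.0}) for n in names]
    return SimulationConfig(seed=seed, haplogroups=hgs, populations=pops,
                            dropout_rate=dropout)


class TestClassifyDataset:
    def test_planted_labels_recovered_noise_free(self):
        ds = simulate_samples(_planted_config(seed=11, n_per_hg=5))
        motifs = infer_motifs([(p, ds.truth[p.sample_id]) for p in ds.profiles],
                              window=ds.window)
        calls, summary = classify_dataset(ds.profiles, motifs)
        counts = {}
        for c in calls:
            counts[c.haplogroup] = counts.get(c.haplogroup, 0) + 1
        assert counts == {"Q": 5, "R": 5}
        assert summary["count"].sum() == len(ds.profiles)

    def test_sample_stripped_of_motif_sites_is_unclassified(self):
        ds = simulate_samples(_planted_config(seed=11, n_per_hg=5))
        motifs = infer_motifs([(p, ds.truth[p.sample_id]) for p in ds.profiles],
                              window=ds.window)
        victim = ds.profiles[0]
        stripped = HaplotypeProfile(victim.sample_id, frozenset(),
                                    victim.window_name)
        calls, _ = classify_dataset([stripped] + ds.profiles[1:], motifs)
        assert calls[0].haplogroup == UNCLASSIFIED
        assert sum(c.haplogroup == UNCLASSIFIED for c in calls) == 1

    def test_input_order_invariance(self):
        ds = simulate_samples(_planted_config(seed=12, n_per_hg=8, rate=0.5))
        motifs = infer_motifs([(p, ds.truth[p.sample_id]) for p in ds.profiles],
                              window=ds.window)
        _, s1 = classify_dataset(ds.profiles, motifs, ds.records)
        order = np.random.default_rng(0).permutation(len(ds.profiles))
        _, s2 = classify_dataset([ds.profiles[i] for i in order], motifs,
                                 [ds.records[i] for i in order])
        assert s1.equals(s2)

    def test_one_site_loss_recovery_with_three_site_motifs(self):
        # near-matching tolerates the loss of one of >= 3 motif sites
        rng = np.random.default_rng(21)
        ds = simulate_samples(_planted_config(seed=21, n_per_hg=50))
        motifs = infer_motifs([(p, ds.truth[p.sample_id]) for p in ds.profiles],
                              window=ds.window)
        degraded = []
        for p in ds.profiles:
            if rng.random() < 0.5 and p.variants:
                lost = sorted(p.variants, key=lambda v: v.position)[
                    rng.integers(len(p.variants))]
                degraded.append(HaplotypeProfile(
                    p.sample_id, p.variants - {lost}, p.window_name,
                    p.missing_positions | {lost.position}))
            else:
                degraded.append(p)
        calls, _ = classify_dataset(degraded, motifs, min_fraction=0.5)
        acc = np.mean([c.haplogroup == ds.truth[c.sample_id] for c in calls])
        assert acc >= 0.95

    def test_unclassified_count_monotone_in_min_fraction(self):
        ds = simulate_samples(_planted_config(seed=13, n_per_hg=40, dropout=0.35))
        clean = simulate_samples(_planted_config(seed=13, n_per_hg=40))
        motifs = infer_motifs([(p, clean.truth[p.sample_id]) for p in clean.profiles],
                              window=clean.window)
        previous = -1
        for frac in (0.3, 0.5, 0.8, 1.0):
            calls, _ = classify_dataset(ds.profiles, motifs, min_fraction=frac)
            n_unc = sum(c.haplogroup == UNCLASSIFIED for c in calls)
            assert n_unc >= previous
            previous = n_unc
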