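"""The adjacent-site screen, Venn overlap, and subject selection."""

import numpy as np
import pytest

from tractome.diversity import wilcoxon_rank_sum
from tractome.migration import (
    adjacent_pair_screen,
    clr_condition_comparison,
    confirm_group_difference,
    paired_evidence,
    screen_all_pairs,
    select_subjects_by_taxon,
    site_overlap,
)
from tractome.profiles_io import SampleMetadata, to_relative_abundance
from tractome.synthetic_data import SyntheticCohortConfig, generate_cohort

from conftest import make_table, paired_table


class TestPairedEvidence:
    def test_defaults(self):
        import inspect

        sig = inspect.signature(paired_evidence)
        assert sig.parameters["lfc_threshold"].default == 0.5
        assert sig.parameters["presence_threshold"].default == 0.0005

    def test_identical_abundance_calls_none(self):
        table = paired_table(
            {"S1": {"CCT": [10, 10], "EMT": [10, 10]}}, ["A sp", "B sp"]
        )
        evidence = paired_evidence(table, "S1", "CCT-EMT")
        assert {e.call for e in evidence} == {"none"}
        assert all(e.log2_diff == 0 for e in evidence)

    def test_directional_calls_from_log2_ratio(self):
        # B doubles downstream (log2 = +1); C halves (log2 = -1);
        # A flat filler keeps totals equal so RA ratios are exact.
        table = paired_table(
            {"S1": {"CCT": [60, 20, 40], "EMT": [60, 40, 20]}},
            ["A sp", "B sp", "C sp"],
        )
        calls = {e.taxon: e.call for e in paired_evidence(table, "S1", "CCT-EMT")}
        assert calls["B sp"] == "up"
        assert calls["C sp"] == "down"
        assert calls["A sp"] == "none"

    def test_one_side_rule_with_presence_threshold(self):
        # upstream RA 0.001 -> one_side_only_down; upstream RA 0.0002 -> omitted
        up = [0, 10, 2, 9988]
        down = [0, 0, 0, 10000]
        table = paired_table(
            {"S1": {"CCT": up, "EMT": down}},
            ["Zero sp", "Present sp", "Faint sp", "Bulk sp"],
        )
        evidence = {e.taxon: e for e in paired_evidence(table, "S1", "CCT-EMT")}
        assert evidence["Present sp"].call == "one_side_only_down"
        assert "Faint sp" not in evidence  # 0.0002 < 0.05%
        assert "Zero sp" not in evidence  # absent at both sites

    def test_missing_site_names_subject_and_site(self):
        table = paired_table({"S1": {"CCT": [1, 1]}}, ["A sp", "B sp"])
        with pytest.raises(KeyError, match="S1.*EMT"):
            paired_evidence(table, "S1", "CCT-EMT")


def _screen_fixture(n_flat=1):
    """Four subjects; 'Grad sp' doubles CCT->EMT in three of them."""
    profiles = {}
    for i in range(3):
        profiles[f"S{i}"] = {"CCT": [60, 20, 120], "EMT": [60, 40, 100]}
    for i in range(3, 3 + n_flat):
        profiles[f"S{i}"] = {"CCT": [60, 20, 120], "EMT": [60, 20, 120]}
    return paired_table(
        profiles, ["Flat sp", "Grad sp", "Filler sp"],
        conditions={f"S{i}": "B" for i in range(3 + n_flat)},
    )


class TestAdjacentPairScreen:
    def test_three_of_four_consistent_passes_at_75(self):
        table = _screen_fixture(n_flat=1)
        findings = adjacent_pair_screen(table, "CCT-EMT", "B")
        by_taxon = {(f.taxon, f.direction): f for f in findings}
        f = by_taxon[("Grad sp", "increased")]
        assert f.n_evaluable == 4
        assert f.n_consistent == 3
        assert f.prevalence_fraction == pytest.approx(0.75)
        assert f.passed  # boundary is inclusive: "at least 75%"

    def test_flat_taxon_absent_from_findings(self):
        table = _screen_fixture()
        findings = adjacent_pair_screen(table, "CCT-EMT", "B")
        assert all(f.taxon != "Flat sp" for f in findings)

    def test_prevalence_default_is_three_quarters(self):
        import inspect

        sig = inspect.signature(adjacent_pair_screen)
        assert sig.parameters["prevalence"].default == 0.75

    def test_direction_symmetry_under_pair_reversal(self):
        table = _screen_fixture()
        forward = adjacent_pair_screen(table, ("CCT", "EMT"), "B")
        backward = adjacent_pair_screen(table, ("EMT", "CCT"), "B")
        fwd = {(f.taxon, f.direction, f.prevalence_fraction) for f in forward}
        flipped = {
            (
                f.taxon,
                "increased" if f.direction == "decreased" else "decreased",
                f.prevalence_fraction,
            )
            for f in backward
        }
        assert fwd == flipped

    def test_thresholds_monotone(self):
        table, _ = generate_cohort(
            SyntheticCohortConfig(
                n_subjects_benign=8, n_subjects_malignant=0, n_taxa=60,
                n_contaminant_taxa=8, n_gradient_taxa=4, n_signature_taxa=0,
                dropout_site_prob=0.0, n_excluded_taxa=0, seed=2,
            )
        )

        def names(lfc=0.5, prev=0.75):
            return {
                (f.taxon, f.direction)
                for f in adjacent_pair_screen(
                    table, "CCT-EMT", "B", lfc_threshold=lfc, prevalence=prev
                )
            }

        base = names()
        assert names(lfc=1.0) <= base
        assert names(prev=0.9) <= base

    def test_invariant_to_sample_row_permutation(self):
        table = _screen_fixture()
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_samples)
        shuffled = table.select_samples(perm)
        a = adjacent_pair_screen(table, "CCT-EMT", "B")
        b = adjacent_pair_screen(shuffled, "CCT-EMT", "B")
        assert sorted(map(repr, a)) == sorted(map(repr, b))

    def test_too_few_evaluable_subjects_rejected(self):
        table = paired_table(
            {"S1": {"CCT": [1, 1], "EMT": [1, 2]}}, ["A sp", "B sp"]
        )
        with pytest.raises(ValueError, match="evaluable"):
            adjacent_pair_screen(table, "CCT-EMT", "B")

    def test_screen_all_pairs_schema_even_when_empty(self):
        table = _screen_fixture()
        df = screen_all_pairs(table, groups=("M",))  # no M subjects
        assert df.empty
        assert "prevalence_fraction" in df.columns


class TestConfirmGroupDifference:
    def test_identical_distributions_p_near_one(self):
        profiles = {
            f"S{i}": {"CCT": [10 + i, 10], "EMT": [10 + i, 10]} for i in range(6)
        }
        table = paired_table(profiles, ["A sp", "B sp"])
        p = confirm_group_difference(table, "A sp", "CCT-EMT", "B")
        assert p > 0.8

    def test_complete_separation_is_significant(self):
        profiles = {}
        for i in range(10):
            profiles[f"S{i}"] = {
                "CCT": [10 + i, 1000],
                "EMT": [200 + i, 1000],
            }
        table = paired_table(profiles, ["Shift sp", "Bulk sp"])
        p = confirm_group_difference(table, "Shift sp", "CCT-EMT", "B")
        assert p < 0.001

    def test_equals_direct_rank_sum_on_extracted_vectors(self):
        table = _screen_fixture()
        ra = to_relative_abundance(table)
        j = table.taxon_index("Grad sp")
        x = [ra[i, j] for i, s in enumerate(table.samples) if s.site == "CCT"]
        y = [ra[i, j] for i, s in enumerate(table.samples) if s.site == "EMT"]
        _, p_direct = wilcoxon_rank_sum(x, y)
        assert confirm_group_difference(table, "Grad sp", "CCT-EMT", "B") == p_direct


class TestSiteOverlap:
    def test_full_overlap_concentrates_in_four_way_region(self):
        vec = [1, 1, 1]
        table = paired_table(
            {"S1": {s: vec for s in ("CCT", "EMT", "FTT", "OCT")}},
            ["A sp", "B sp", "C sp"],
        )
        regions = site_overlap(table)
        assert regions[("CCT", "EMT", "FTT", "OCT")] == 3
        assert sum(regions.values()) == 3

    def test_hand_built_sets_match_manual_arithmetic(self):
        # A: everywhere; B: CCT+EMT; C: CCT only; D: OCT only; E: nowhere
        table = paired_table(
            {
                "S1": {
                    "CCT": [1, 1, 1, 0, 0],
                    "EMT": [1, 1, 0, 0, 0],
                    "FTT": [1, 0, 0, 0, 0],
                    "OCT": [1, 0, 0, 1, 0],
                }
            },
            ["A sp", "B sp", "C sp", "D sp", "E sp"],
        )
        regions = site_overlap(table)
        assert regions[("CCT", "EMT", "FTT", "OCT")] == 1  # A
        assert regions[("CCT", "EMT")] == 1  # B
        assert regions[("CCT",)] == 1  # C
        assert regions[("OCT",)] == 1  # D
        assert sum(regions.values()) == 4  # E detected nowhere

    def test_partition_sums_to_union_on_random_table(self):
        rng = np.random.default_rng(8)
        sites = ["CCT", "EMT", "FTT", "OCT"] * 4
        subjects = [f"S{i // 4}" for i in range(16)]
        counts = rng.integers(0, 3, size=(16, 30))
        table = make_table(counts, sites=sites, subjects=subjects)
        regions = site_overlap(table)
        union = int(((counts > 0).any(axis=0)).sum())
        assert sum(regions.values()) == union

    def test_empty_site_logged_and_empty(self, caplog):
        table = paired_table({"S1": {"CCT": [1, 1]}}, ["A sp", "B sp"])
        with caplog.at_level("WARNING", logger="tractome"):
            regions = site_overlap(table)
        assert regions[("CCT",)] == 2
        assert "no samples" in caplog.text


class TestSelectSubjectsByTaxon:
    def test_default_threshold_is_one_percent(self):
        import inspect

        sig = inspect.signature(select_subjects_by_taxon)
        assert sig.parameters["threshold"].default == 0.01

    def test_absent_taxon_gives_empty_list(self):
        table = paired_table(
            {"S1": {"CCT": [0, 100]}, "S2": {"CCT": [0, 50]}}, ["A sp", "B sp"]
        )
        assert select_subjects_by_taxon(table, "A sp") == []

    def test_exactly_the_exceeding_subjects_returned(self):
        profiles = {
            "S1": {"CCT": [5, 95]},       # 5% -> selected
            "S2": {"CCT": [1, 999]},      # 0.1%
            "S3": {"CCT": [0, 100], "EMT": [2, 98]},  # 2% at EMT -> selected
            "S4": {"CCT": [1, 99]},       # exactly 1%: strict > excludes
            "S5": {"CCT": [0, 10]},
        }
        table = paired_table(profiles, ["Target sp", "Other sp"])
        assert select_subjects_by_taxon(table, "Target sp") == ["S1", "S3"]

    def test_unknown_taxon_lists_near_matches(self):
        table = paired_table({"S1": {"CCT": [1, 1]}}, ["Targett sp", "Other sp"])
        with pytest.raises(KeyError, match="Targett sp"):
            select_subjects_by_taxon(table, "Target sp")


class TestClrConditionComparison:
    def test_planted_condition_signal_detected(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 150, size=(12, 6))
        counts[6:, 0] *= 8  # taxon 0 enriched in M
        sites = ["OCT"] * 12
        table = make_table(
            counts, sites=sites, conditions=["B"] * 6 + ["M"] * 6,
        )
        df = clr_condition_comparison(table, "OCT")
        row = df[df.taxon == table.taxon_names[0]].iloc[0]
        assert row.median_clr_M > row.median_clr_B
        assert row.p_value == df.p_value.min()

    def test_single_condition_site_rejected(self):
        table = make_table([[1, 1]], sites=["OCT"], conditions=["B"])
        with pytest.raises(ValueError, match="one condition"):
            clr_condition_comparison(table, "OCT")
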