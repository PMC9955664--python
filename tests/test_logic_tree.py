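import pytest

from moha.harmonization import TreeConfig, harmonize_cohort
from moha.logic_tree import (
    ALL_BRANCH_IDS,
    MOTHERS_DISABLED_BRANCHES,
    SWITCHER_BRANCH_IDS,
    MohaAllocation,
    affirmatory_summary,
    allocate,
    allocate_cohort,
    count_affirmatory_factors,
    exit_frequency_table,
    gateway,
    mothers_tree_config,
    run_sexual_arm,
    run_vertical_arm,
)


class TestGateway:
    def test_no_activity_no_abuse_goes_vertical(self, profile_factory):
        assert gateway(profile_factory()) == "vertical"

    def test_abuse_only_goes_sexual(self, profile_factory):
        assert gateway(profile_factory(ever_sexual_abuse=True)) == "sexual"

    def test_activity_goes_sexual(self, profile_factory):
        assert gateway(profile_factory(ever_sexual_activity=True)) == "sexual"

    def test_forced_gateway(self, profile_factory):
        config = TreeConfig(force_sexual_gateway=True)
        assert gateway(profile_factory(), config) == "sexual"


class TestSexualArm:
    def test_debut_before_art_exits_s1(self, profile_factory):
        profile = profile_factory(sexual_debut_age=13, art_init_age=15, ever_sexual_activity=True)
        assert run_sexual_arm(profile) == ("sexual", "S1")

    def test_debut_before_first_test_exits_s1(self, profile_factory):
        profile = profile_factory(sexual_debut_age=13, first_hiv_test_age=14)
        assert run_sexual_arm(profile) == ("sexual", "S1")

    def test_debut_after_both_references_not_s1(self, profile_factory):
        profile = profile_factory(
            sexual_debut_age=15, art_init_age=5, first_hiv_test_age=4, hiv_status_aware=True
        )
        assert run_sexual_arm(profile) == ("sexual", "S6")

    def test_abuse_exits_s2(self, profile_factory):
        assert run_sexual_arm(profile_factory(ever_sexual_abuse=True)) == ("sexual", "S2")

    @pytest.mark.parametrize(
        "factor,branch",
        [
            ("discordant_disclosure", "S3"),
            ("consistent_unprotected_sex", "S4"),
            ("other_risky_behaviour", "S5"),
            ("hiv_status_aware", "S6"),
        ],
    )
    def test_remaining_exits(self, profile_factory, factor, branch):
        assert run_sexual_arm(profile_factory(**{factor: True})) == ("sexual", branch)

    def test_fall_through(self, profile_factory):
        assert run_sexual_arm(profile_factory(ever_sexual_activity=True)) is None


class TestVerticalArm:
    @pytest.mark.parametrize(
        "overrides,branch",
        [
            (dict(maternal_hiv_orphan=True), "V1"),
            (dict(mother_on_art=True), "V2"),
            (dict(maternal_orphan_le10_presumed=True), "V3"),
            (dict(cognitive_delay=True), "V4"),
            (dict(poor_physical_health=True), "V5"),
            (dict(paternal_hiv_orphan_or_dad_art=True), "V6"),
            (dict(paternal_orphan_le10_presumed=True), "V7"),
            (dict(art_init_age=4, art_init_year=2003), "V8"),
            (dict(first_hiv_test_age=8), "V9"),
        ],
    )
    def test_exit_order(self, profile_factory, overrides, branch):
        assert run_vertical_arm(profile_factory(**overrides)) == ("vertical", branch)

    def test_slow_progressor(self, profile_factory):
        profile = profile_factory(art_naive=True, first_hiv_test_age=8)
        assert run_vertical_arm(profile) == ("vertical", "SLOW")

    def test_branch_priority_first_hit(self, profile_factory):
        profile = profile_factory(maternal_hiv_orphan=True, cognitive_delay=True)
        assert run_vertical_arm(profile) == ("vertical", "V1")

    def test_switcher_sees_only_starred_branches(self, profile_factory):
        profile = profile_factory(cognitive_delay=True)  # V4: not offered to switchers
        assert run_vertical_arm(profile, switcher=True) is None
        profile = profile_factory(maternal_hiv_orphan=True)
        assert run_vertical_arm(profile, switcher=True) == ("vertical", "V1")

    def test_rollout_year_boundary(self, profile_factory):
        assert run_vertical_arm(profile_factory(art_init_age=7, art_init_year=2004)) == (
            "vertical", "V8",
        )
        assert run_vertical_arm(profile_factory(art_init_age=7, art_init_year=2005)) is None


class TestAllocate:
    def test_sexual_with_countering_vertical_evidence(self, profile_factory):
        profile = profile_factory(
            sexual_debut_age=13, art_init_age=15, ever_sexual_activity=True,
            maternal_hiv_orphan=True,
        )
        allocation = allocate(profile)
        assert (allocation.label, allocation.exit_branch) == ("sexual", "S1")
        assert "V1" in allocation.conflict_flags

    def test_zero_informative_factors_unclassified(self, profile_factory):
        allocation = allocate(profile_factory())
        assert allocation.label == "unclassified"
        assert allocation.exit_branch is None
        assert allocation.affirmatory_count == 0

    def test_vertical_arm_direct(self, profile_factory):
        allocation = allocate(profile_factory(mother_on_art=True))
        assert (allocation.label, allocation.exit_branch) == ("vertical", "V2")
        assert allocation.arm_entered == "vertical"
        assert allocation.switched is False

    def test_switch_from_sexual_to_vertical(self, profile_factory):
        # sexually active but no sexual-arm factor fires; maternal orphan catches it
        profile = profile_factory(
            ever_sexual_activity=True, sexual_debut_age=16, art_init_age=5,
            first_hiv_test_age=4, maternal_hiv_orphan=True,
        )
        allocation = allocate(profile)
        assert allocation.label == "vertical"
        assert allocation.arm_entered == "sexual"
        assert allocation.switched is True
        assert allocation.exit_branch in SWITCHER_BRANCH_IDS

    def test_sexual_fall_through_with_unstarred_vertical_factor_only(self, profile_factory):
        profile = profile_factory(ever_sexual_activity=True, sexual_debut_age=16,
                                  art_init_age=5, cognitive_delay=True)
        assert allocate(profile).label == "unclassified"

    def test_determinism(self, profile_factory):
        profile = profile_factory(ever_sexual_abuse=True, maternal_hiv_orphan=True)
        assert allocate(profile) == allocate(profile)

    def test_first_hit_semantics_deleting_later_branches(self, profile_factory):
        """Disabling any branch strictly after the exit leaves the allocation
        unchanged."""
        profile = profile_factory(
            ever_sexual_activity=True, sexual_debut_age=13, art_init_age=15,
            consistent_unprotected_sex=True, hiv_status_aware=True,
        )
        full = allocate(profile)
        assert full.exit_branch == "S1"
        for removed in ("S2", "S3", "S4", "S5", "S6"):
            config = TreeConfig(enabled_branches=frozenset(ALL_BRANCH_IDS - {removed}))
            trimmed = allocate(profile, config)
            assert (trimmed.label, trimmed.exit_branch) == (full.label, full.exit_branch)

    def test_labels_partition(self, default_synthetic, default_tree_config):
        _, (participants, waves, medical, _) = default_synthetic
        cohort = [p for p in participants if not p.single_wave_sample]
        profiles = harmonize_cohort(cohort, waves, medical, default_tree_config)
        allocations = allocate_cohort(profiles, default_tree_config)
        assert len(allocations) == len(cohort)
        labels = {a.label for a in allocations}
        assert labels <= {"vertical", "sexual", "unclassified"}
        for a in allocations:
            assert (a.label == "unclassified") == (a.exit_branch is None)
            if a.switched:
                assert a.arm_entered == "sexual" and a.label == "vertical"
                assert a.exit_branch in SWITCHER_BRANCH_IDS
            if a.label != "unclassified":
                assert a.affirmatory_count >= 1


class TestAffirmatoryCount:
    def test_three_sexual_factors(self, profile_factory):
        profile = profile_factory(
            sexual_debut_age=13, art_init_age=15, ever_sexual_activity=True,
            consistent_unprotected_sex=True, hiv_status_aware=True,
        )
        assert count_affirmatory_factors(profile, "sexual") == 3  # S1, S4, S6

    def test_single_factor_lower_bound(self, profile_factory):
        assert count_affirmatory_factors(profile_factory(ever_sexual_abuse=True), "sexual") == 1

    def test_mutually_exclusive_in_data_still_pure_sum(self, profile_factory):
        # V1 and V2 cannot co-occur in real data but the count is a pure
        # sum of predicates
        profile = profile_factory(maternal_hiv_orphan=True, mother_on_art=True)
        assert count_affirmatory_factors(profile, "vertical") == 2

    def test_disabled_branches_not_counted(self, profile_factory):
        profile = profile_factory(discordant_disclosure=True, ever_sexual_abuse=True)
        config = mothers_tree_config()
        assert count_affirmatory_factors(profile, "sexual", config) == 1  # S3 disabled


class TestMothersVariant:
    def test_config_shape(self):
        config = mothers_tree_config()
        assert config.force_sexual_gateway is True
        assert config.enabled_branches == ALL_BRANCH_IDS - MOTHERS_DISABLED_BRANCHES

    def test_forced_gateway_and_disabled_branches(self, profile_factory):
        config = mothers_tree_config()
        # no sexual activity reported, yet enters (and exits) the sexual arm
        allocation = allocate(profile_factory(consistent_unprotected_sex=True), config)
        assert allocation.arm_entered == "sexual"
        assert (allocation.label, allocation.exit_branch) == ("sexual", "S4")
        # S3 is disabled: a discordant-only profile cannot exit there
        allocation = allocate(profile_factory(discordant_disclosure=True), config)
        assert allocation.exit_branch != "S3"


class TestExitFrequencyTable:
    def test_counts(self):
        allocations = [
            MohaAllocation("A", "sexual", "sexual", "S1", False, 1),
            MohaAllocation("B", "sexual", "sexual", "S1", False, 2),
            MohaAllocation("C", "vertical", "vertical", "V1", False, 1),
        ]
        table = exit_frequency_table(allocations).set_index("exit_branch")["n"]
        assert table["S1"] == 2
        assert table["V1"] == 1
        assert table["total_sexual"] == 2
        assert table["total_vertical"] == 1
        assert table["unclassified"] == 0

    def test_totals_conservation(self, default_synthetic, default_tree_config):
        _, (participants, waves, medical, _) = default_synthetic
        cohort = [p for p in participants if not p.single_wave_sample]
        profiles = harmonize_cohort(cohort, waves, medical, default_tree_config)
        table = exit_frequency_table(allocate_cohort(profiles, default_tree_config))
        for label in ("sexual", "vertical"):
            branches = table[(table["label"] == label) & (table["exit_branch"] != f"total_{label}")]
            total = table[table["exit_branch"] == f"total_{label}"]["n"].item()
            assert branches["n"].sum() == total


class TestAffirmatorySummary:
    @staticmethod
    def _alloc(pid, count):
        return MohaAllocation(pid, "sexual", "sexual", "S2", False, count)

    def test_constant_counts(self, profile_factory):
        allocations = [self._alloc(f"P{i}", 3) for i in range(3)]
        profiles = [profile_factory(f"P{i}", ever_sexual_abuse=True) for i in range(3)]
        summary = affirmatory_summary(allocations, profiles)
        row = summary[summary["factor"] == "__arm_total__"].iloc[0]
        assert row["mean_affirmatory"] == pytest.approx(3.0)
        assert row["sd_affirmatory"] == pytest.approx(0.0)

    def test_sample_sd_uses_n_minus_1(self, profile_factory):
        allocations = [self._alloc(f"P{i}", c) for i, c in enumerate((1, 2, 3))]
        profiles = [profile_factory(f"P{i}", ever_sexual_abuse=True) for i in range(3)]
        row = affirmatory_summary(allocations, profiles)
        row = row[row["factor"] == "__arm_total__"].iloc[0]
        assert row["mean_affirmatory"] == pytest.approx(2.0)
        assert row["sd_affirmatory"] == pytest.approx(1.0)

    def test_empty_arm_omitted(self, profile_factory):
        allocations = [self._alloc("P0", 1)]
        summary = affirmatory_summary(allocations, [profile_factory("P0", ever_sexual_abuse=True)])
        assert set(summary["arm"]) == {"sexual"}

    def test_per_factor_counts(self, profile_factory):
        profiles = [
            profile_factory("P0", ever_sexual_abuse=True, hiv_status_aware=True),
            profile_factory("P1", ever_sexual_abuse=True),
        ]
        allocations = [self._alloc("P0", 2), self._alloc("P1", 1)]
        summary = affirmatory_summary(allocations, profiles).set_index("factor")
        assert summary.loc["S2", "n"] == 2
        assert summary.loc["S6", "n"] == 1
        assert summary.loc["S6", "pct"] == pytest.approx(50.0)
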