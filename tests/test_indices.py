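"""Consensus and fidelity statistics."""

import math
from collections import Counter, defaultdict

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnokit._round import round_half_up
from ethnokit.datasets import (
    GAYASAN_DEMOGRAPHICS,
    SIX_ROW_BARLEY_AILMENTS,
)
from ethnokit.errors import DomainError, ValidationError
from ethnokit.indices import (
    ailment_breadth,
    category_consensus_table,
    compute_fl,
    compute_icf,
    family_summary,
    fidelity_table,
    fl100_species,
    flora_coverage,
    usage_summary,
)
from ethnokit.simulate import generate_survey

from conftest import make_report, small_config


class TestComputeIcf:
    @pytest.mark.parametrize("nur,nt,expected", [
        (2142, 49, 0.98),   # highest-consensus category of the survey
        (138, 14, 0.91),    # lowest-consensus category
        (165, 10, 0.95),    # requires round-half-up at the third decimal
    ])
    def test_published_category_values(self, nur, nt, expected):
        assert round_half_up(compute_icf(nur, nt), 2) == expected

    @pytest.mark.parametrize("k", [2, 5, 100])
    def test_zero_consensus_when_every_citation_is_a_new_species(self, k):
        assert compute_icf(k, k) == 0.0

    def test_perfect_consensus_single_species(self):
        assert compute_icf(100, 1) == 1.0

    def test_degenerate_single_citation_returns_zero(self):
        assert compute_icf(1, 1) == 0.0

    @pytest.mark.parametrize("nur,nt", [(5, 6), (5, 0), (0, 1)])
    def test_domain_errors(self, nur, nt):
        with pytest.raises(DomainError):
            compute_icf(nur, nt)

    @given(nur=st.integers(2, 10_000), nt=st.integers(1, 10_000))
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_extremes(self, nur, nt):
        if nt > nur:
            nt = nur
        icf = compute_icf(nur, nt)
        assert 0.0 <= icf <= 1.0
        assert (icf == 1.0) == (nt == 1 and nur >= 2)
        assert (icf == 0.0) == (nt == nur)

    @given(nur=st.integers(2, 5_000), nt=st.integers(1, 5_000),
           r=st.integers(2, 10))
    @settings(derandomize=True, max_examples=200)
    def test_replication_increases_and_new_species_decreases(self, nur, nt, r):
        nt = min(nt, nur)
        icf = compute_icf(nur, nt)
        # replicating every report r times sharpens consensus
        assert compute_icf(r * nur, nt) > icf or icf == 1.0
        # a report citing a brand-new species weakly dilutes it
        assert compute_icf(nur + 1, nt + 1) <= icf


class TestCategoryConsensusTable:
    def test_hand_enumerated_category(self, tiny_reports):
        table = category_consensus_table(tiny_reports)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["nt"], row["nur"]) == (2, 3)
        assert row["icf"] == pytest.approx(0.5)
        assert not row["degenerate"]

    def test_single_report_category_is_degenerate(self):
        table = category_consensus_table(
            [make_report("i1", "sA", "cough", category="Others")])
        row = table.iloc[0]
        assert (row["nt"], row["nur"], row["icf"]) == (1, 1, 0.0)
        assert bool(row["degenerate"])

    def test_uncategorised_reports_rejected(self):
        with pytest.raises(ValidationError):
            category_consensus_table([make_report("i1", "sA", "cough")])

    def test_sorted_by_icf_then_nur_then_label(self, small_survey):
        table = category_consensus_table(small_survey.reports)
        keys = list(zip(-table["icf"], -table["nur"], table["category"]))
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_recount(self, seed):
        result = generate_survey(small_config(seed=seed, n_informants=12))
        table = category_consensus_table(result.reports)
        # independent single-pass tally
        nur = Counter(r.category for r in result.reports)
        species = defaultdict(set)
        for r in result.reports:
            species[r.category].add(r.species_id)
        for _, row in table.iterrows():
            cat = row["category"]
            assert row["nur"] == nur[cat]
            assert row["nt"] == len(species[cat])
            expected = ((nur[cat] - len(species[cat])) / (nur[cat] - 1)
                        if nur[cat] > 1 else 0.0)
            assert row["icf"] == pytest.approx(expected)

    def test_high_consensus_limit_approaches_one(self):
        result = generate_survey(
            small_config(seed=77, concentration=1e-6, n_categories=1,
                         pool_size=30, intensity=2.0, n_informants=100))
        table = category_consensus_table(result.reports)
        assert table["icf"].iloc[0] == 1.0


class TestFidelity:
    def test_sole_use_and_closed_forms(self):
        assert compute_fl(1, 1) == 100.0
        assert compute_fl(1, 2) == 50.0
        assert compute_fl(3, 4) == 75.0

    def test_domain_errors(self):
        for np_, n in [(0, 1), (5, 4)]:
            with pytest.raises(DomainError):
                compute_fl(np_, n)

    def test_two_ailment_split(self):
        reports = [make_report(f"i{k}", "sA", "cough") for k in range(3)]
        reports.append(make_report("i9", "sA", "burn"))
        table = fidelity_table(reports)
        assert dict(zip(table["ailment"], table["fl"])) == {
            "cough": 75.0, "burn": 25.0}

    def test_single_ailment_is_100(self):
        table = fidelity_table([make_report("i1", "sA", "cough")])
        assert list(table["fl"]) == [100.0]

    def test_empty_input_empty_output(self):
        assert fidelity_table([]).empty

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property_exact_at_full_precision(self, seed):
        result = generate_survey(small_config(seed=seed, n_informants=15))
        table = fidelity_table(result.reports)
        for _, group in table.groupby("species_id"):
            assert group["np"].sum() == group["n"].iloc[0]
            assert math.isclose(group["fl"].sum(), 100.0, abs_tol=1e-9)
            assert abs(group["fl_2dp"].sum() - 100.0) <= 0.05 * len(group)

    def test_matches_generator_pair_counts(self, small_survey):
        table = fidelity_table(small_survey.reports)
        observed = {(row["species_id"], row["ailment"]): row["np"]
                    for _, row in table.iterrows()}
        assert observed == small_survey.ledger.pair_counts

    def test_informant_basis_differs_when_informants_repeat(self):
        reports = [make_report("i1", "sA", "cough"),
                   make_report("i1", "sA", "burn"),
                   make_report("i2", "sA", "cough")]
        by_reports = fidelity_table(reports, basis="reports")
        by_informants = fidelity_table(reports, basis="informants")
        cough_r = by_reports.set_index("ailment").loc["cough"]
        cough_i = by_informants.set_index("ailment").loc["cough"]
        assert cough_r["n"] == 3 and cough_i["n"] == 2
        assert cough_i["fl"] == 100.0


class TestFl100:
    def test_min_reports_threshold(self):
        fid = fidelity_table([
            make_report(f"i{k}", "sA", "cough") for k in range(5)
        ] + [make_report("i1", "sB", "burn")])
        assert fl100_species(fid, min_reports=2) == {"sA"}
        assert fl100_species(fid, min_reports=1) == {"sA", "sB"}

    def test_multi_ailment_species_excluded(self):
        fid = fidelity_table([make_report("i1", "sA", "cough"),
                              make_report("i2", "sA", "burn")])
        assert fl100_species(fid) == set()

    def test_generator_single_ailment_species_bookkeeping(self):
        forced = generate_survey(small_config(
            seed=3, n_informants=20, n_categories=2, pool_size=6,
            intensity=1.0))
        table = fidelity_table(forced.reports)
        totals = forced.ledger.species_totals()
        ailments = forced.ledger.species_ailments()
        expected = {sid for sid, n in totals.items()
                    if n >= 2 and len(ailments[sid]) == 1}
        assert fl100_species(table, min_reports=2) == expected


class TestSummaries:
    def test_family_percentages(self, species_table):
        reports = [make_report("i1", "sA", "cough"),
                   make_report("i2", "sA", "cough"),
                   make_report("i1", "sB", "burn")]
        table = family_summary(reports, species_table)
        rosaceae = table.set_index("family").loc["Rosaceae"]
        assert rosaceae["n_species"] == 1
        assert rosaceae["pct_species"] == pytest.approx(50.0)
        assert rosaceae["pct_reports"] == pytest.approx(200 / 3)

    def test_single_family_is_100_percent(self, species_table):
        reports = [make_report("i1", "sA", "cough")]
        table = family_summary(reports, species_table)
        assert list(table["pct_species"]) == [100.0]

    def test_unknown_species_rejected(self, species_table):
        with pytest.raises(ValidationError):
            family_summary([make_report("i1", "sZ", "x")], species_table)

    def test_family_counts_match_generator_assignment(self, small_survey):
        table = family_summary(small_survey.reports,
                               small_survey.species_table)
        cited = {r.species_id for r in small_survey.reports}
        expected = Counter(small_survey.ledger.family_of[s] for s in cited)
        assert dict(zip(table["family"], table["n_species"])) == expected

    def test_usage_axis_counts_attribute_occurrences(self):
        reports = [make_report("i1", "sA", "a", parts=("stem",)),
                   make_report("i2", "sA", "a2", parts=("stem",)),
                   make_report("i3", "sA", "a3", parts=("root",))]
        table = usage_summary(reports, "plant_part")
        assert len(table) == 2  # distinct labels
        stem = table.set_index("key").loc["stem"]
        assert stem["count"] == 2
        assert stem["pct"] == pytest.approx(200 / 3)

    def test_route_axis_even_split(self):
        reports = [make_report(f"i{k}", "sA", f"a{k}", routes=("oral",))
                   for k in range(5)]
        reports += [make_report(f"j{k}", "sB", f"b{k}", routes=("topical",))
                    for k in range(5)]
        table = usage_summary(reports, "route")
        assert set(table["pct"]) == {50.0}

    def test_invalid_axis(self):
        with pytest.raises(DomainError):
            usage_summary([], "dosage")

    def test_distinct_labels_match_generator_pool_usage(self, small_survey):
        for axis in ("plant_part", "preparation", "route"):
            table = usage_summary(small_survey.reports, axis)
            tally = small_survey.ledger.attribute_tallies[axis]
            assert dict(zip(table["key"], table["count"])) == dict(tally)

    def test_pct_sums_to_100(self, small_survey):
        for axis in ("plant_part", "preparation", "route"):
            table = usage_summary(small_survey.reports, axis)
            assert table["pct"].sum() == pytest.approx(100.0)


class TestBreadthAndCoverage:
    def test_distinct_ailments_deduplicated(self):
        reports = [make_report("i1", "sA", "a"),
                   make_report("i2", "sA", "b"),
                   make_report("i3", "sA", "a")]
        assert ailment_breadth(reports)["sA"] == 2

    def test_empty(self):
        assert ailment_breadth([]).empty

    def test_transcribed_barley_row_has_36_ailments(self):
        reports = [make_report(f"i{k}", "S87", ailment)
                   for k, ailment in enumerate(SIX_ROW_BARLEY_AILMENTS)]
        assert ailment_breadth(reports)["S87"] == 36

    def test_flora_coverage_published_and_edge_values(self):
        d = GAYASAN_DEMOGRAPHICS
        assert round_half_up(flora_coverage(
            d["n_medicinal_species"], d["n_flora_species"]), 1) == 36.9
        assert flora_coverage(0, 542) == 0.0
        assert flora_coverage(542, 542) == 100.0
        with pytest.raises(DomainError):
            flora_coverage(10, 0)
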