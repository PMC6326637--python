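"""The Markov cohort engine: single steps, multi-year projection, flows."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hwforecast as hw
from hwforecast.categories import CATEGORIES, N_CATEGORIES, PAIRS


def zero_tp():
    return hw.TransitionTable(np.zeros(10), np.zeros(10))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestLadder:
    def test_eleven_strictly_ordered_categories(self):
        assert len(CATEGORIES) == 11
        ranks = [hw.as_category(c).rank for c in CATEGORIES]
        assert ranks == sorted(set(ranks))

    def test_only_one_rung_up_and_absorbing_top(self):
        for code in CATEGORIES[:-1]:
            assert hw.as_category(code).successor.rank == hw.as_category(code).rank + 1
        assert hw.as_category("EsTH").successor is None

    def test_unknown_code_rejected(self):
        with pytest.raises(hw.ValidationError, match="unknown facility category"):
            hw.as_category("HOSPITAL")


class TestTransitionTable:
    def test_from_pairs_requires_all_ten(self, ghana_tp):
        entries = {p: (ghana_tp.probability(*p), ghana_tp.standard_error(*p))
                   for p in PAIRS}
        del entries[("RH", "EmTH")]
        with pytest.raises(hw.ValidationError, match="missing transition pair"):
            hw.TransitionTable.from_pairs(entries)

    def test_non_adjacent_pair_rejected(self, ghana_tp):
        with pytest.raises(hw.ValidationError, match="adjacent"):
            ghana_tp.probability("CHPS", "HCB")

    @pytest.mark.parametrize("p", [-0.1, 1.1, np.nan])
    def test_probability_bounds_enforced(self, p):
        probs = np.full(10, 0.5)
        probs[3] = p
        with pytest.raises(hw.ValidationError):
            hw.TransitionTable(probs, np.zeros(10))


class TestCensusContainer:
    def test_negative_counts_rejected(self):
        counts = {("R1", cat, 2016): 1.0 for cat in CATEGORIES}
        counts[("R1", "HCA", 2016)] = -2.0
        with pytest.raises(hw.ValidationError):
            hw.FacilityCensus.from_mapping(counts, baseline_year=2016)

    def test_national_sums_regions(self, ghana_census):
        two = hw.split_census(ghana_census, 2)
        np.testing.assert_allclose(two.national(2016), ghana_census.national(2016))

    def test_round_trip_frame(self, ghana_census):
        df = ghana_census.to_frame()
        back = hw.FacilityCensus.from_frame(df, baseline_year=2016)
        np.testing.assert_array_equal(back.vector("Ghana", 2016),
                                      ghana_census.vector("Ghana", 2016))


# ---------------------------------------------------------------------------
# CHPS demarcation
# ---------------------------------------------------------------------------

class TestDemarcation:
    def test_exact_division(self):
        pop = hw.PopulationSeries({("R1", 2016): 1_500_000})
        assert hw.demarcate_chps(pop, "R1", 2016) == 1000.0

    def test_unrounded_quotient(self):
        pop = hw.PopulationSeries({("R1", 2016): 987_654})
        assert hw.demarcate_chps(pop, "R1", 2016) == pytest.approx(658.436)

    def test_zero_population_rejected(self):
        with pytest.raises(hw.ValidationError, match="population must be > 0"):
            hw.PopulationSeries({("R1", 2016): 0})

    def test_missing_cell_named_in_error(self):
        pop = hw.PopulationSeries({("R1", 2016): 1000.0})
        with pytest.raises(hw.MissingDataError, match="R1.*2017"):
            hw.demarcate_chps(pop, "R1", 2017)


# ---------------------------------------------------------------------------
# one annual cycle
# ---------------------------------------------------------------------------

class TestStepCensus:
    def test_published_one_step_values(self, ghana_tp):
        nxt = hw.step_census(hw.ghana_baseline_counts(), ghana_tp)
        assert nxt["PHB"] == pytest.approx(58.711)   # 49 - 6.321 + 16.032
        assert nxt["HCB"] == pytest.approx(183.375)  # 158 - 4.424 + 29.799
        assert nxt["PHD"] == pytest.approx(16.142)
        assert nxt["EsTH"] == pytest.approx(2.002)   # absorbing: inflow only

    def test_zero_probabilities_identity(self):
        base = hw.ghana_baseline_counts()
        assert hw.step_census(base, zero_tp()) == pytest.approx(base)

    def test_construction_added_after_transition(self, ghana_tp):
        base = hw.ghana_baseline_counts()
        plain = hw.step_census(base, ghana_tp)
        built = hw.step_census(base, ghana_tp, construction_year={"RH": 2.0})
        # new facilities appear in the end-of-year census without transitioning
        assert built["RH"] == pytest.approx(plain["RH"] + 2.0)
        assert built["EmTH"] == pytest.approx(plain["EmTH"])

    def test_chps_next_overrides_markov_rule(self, ghana_tp):
        base = hw.ghana_baseline_counts()
        nxt = hw.step_census(base, ghana_tp, chps_next=5000.0)
        assert nxt["CHPS"] == 5000.0
        # HCA inflow still uses the current CHPS stock
        assert nxt["HCA"] == pytest.approx(903 - 903 * 0.033 + 4449 * 0.010)

    def test_negative_input_rejected(self, ghana_tp):
        base = hw.ghana_baseline_counts()
        base["PHA"] = -1.0
        with pytest.raises(hw.ValidationError):
            hw.step_census(base, ghana_tp)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        counts=st.lists(st.floats(0, 1e4), min_size=11, max_size=11),
        probs=st.lists(st.floats(0, 1), min_size=10, max_size=10),
    )
    def test_nonnegativity_and_conservation(self, counts, probs):
        """Any valid state stays non-negative and conserves total mass."""
        tp = hw.TransitionTable(np.array(probs), np.zeros(10))
        nxt = hw.step_census(np.array(counts), tp)
        vals = np.array([nxt[c] for c in CATEGORIES])
        assert np.all(vals >= 0)
        assert vals.sum() == pytest.approx(sum(counts), rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# multi-year projection
# ---------------------------------------------------------------------------

class TestProject:
    def test_published_one_step_census(self, ghana_census, ghana_tp):
        proj = hw.project(ghana_census, ghana_tp, horizon=1)
        assert proj.get("Ghana", "PHD", 2017) == pytest.approx(16.142)

    def test_zero_probabilities_constant(self, ghana_census):
        proj = hw.project(ghana_census, zero_tp(), horizon=10)
        for year in range(2016, 2027):
            np.testing.assert_allclose(proj.national(year),
                                       ghana_census.national(2016))

    def test_linearity_over_region_partition(self, ghana_census, ghana_tp):
        """National sums of a split-region run equal the single-region run."""
        split = hw.split_census(ghana_census, 2)
        p1 = hw.project(ghana_census, ghana_tp, horizon=5)
        p2 = hw.project(split, ghana_tp, horizon=5)
        for year in range(2016, 2022):
            np.testing.assert_allclose(p2.national(year), p1.national(year),
                                       rtol=1e-12)

    def test_conservation_without_construction(self, ghana_census, ghana_tp):
        proj = hw.project(ghana_census, ghana_tp, horizon=10)
        total0 = ghana_census.national(2016).sum()
        for year in range(2017, 2027):
            assert proj.national(year).sum() == pytest.approx(total0, rel=1e-9)

    def test_absorbing_top_category_nondecreasing(self, ghana_census, ghana_tp):
        proj = hw.project(ghana_census, ghana_tp, horizon=10)
        top = [proj.get("Ghana", "EsTH", y) for y in range(2016, 2027)]
        assert all(b >= a for a, b in zip(top, top[1:]))

    def test_population_mode_sets_chps(self, ghana_census, ghana_tp):
        pop = hw.PopulationSeries(
            {("Ghana", y): 30_000_000.0 for y in range(2016, 2027)})
        proj = hw.project(ghana_census, ghana_tp, pop=pop, horizon=3)
        for year in (2017, 2018, 2019):
            assert proj.get("Ghana", "CHPS", year) == pytest.approx(20000.0)

    def test_horizon_below_one_rejected(self, ghana_census, ghana_tp):
        with pytest.raises(hw.ValidationError, match="horizon"):
            hw.project(ghana_census, ghana_tp, horizon=0)

    def test_unknown_construction_region_rejected(self, ghana_census, ghana_tp):
        cons = hw.ConstructionSchedule.from_mapping({("Mars", "CHPS", 2017): 1.0})
        with pytest.raises(hw.ValidationError, match="unknown region"):
            hw.project(ghana_census, ghana_tp, cons=cons, horizon=1)

    def test_construction_feeds_later_transitions(self, ghana_census, ghana_tp):
        cons = hw.ConstructionSchedule.from_mapping({("Ghana", "RH", 2017): 3.0})
        proj = hw.project(ghana_census, ghana_tp, cons=cons, horizon=2)
        plain = hw.project(ghana_census, ghana_tp, horizon=2)
        # extra RH stock only starts producing EmTH inflow the following year
        assert proj.get("Ghana", "EmTH", 2017) == pytest.approx(
            plain.get("Ghana", "EmTH", 2017))
        assert proj.get("Ghana", "EmTH", 2018) == pytest.approx(
            plain.get("Ghana", "EmTH", 2018) + 3.0 * 0.091)


# ---------------------------------------------------------------------------
# transition flows
# ---------------------------------------------------------------------------

class TestFlows:
    def test_published_year0_flows(self, ghana_census, ghana_tp):
        flows = hw.transition_flows(ghana_census, ghana_tp)
        assert flows.flow("PHA", "PHB", 2016) == pytest.approx(16.032)
        assert flows.flow("PHC", "PHD", 2016) == pytest.approx(2.436)

    def test_zero_count_zero_flow(self, ghana_tp):
        counts = {("R1", cat, 2016): 0.0 for cat in CATEGORIES}
        census = hw.FacilityCensus.from_mapping(counts, 2016)
        flows = hw.transition_flows(census, ghana_tp)
        assert (flows.flows.to_numpy() == 0).all()

    def test_totals_sum_years(self, ghana_census, ghana_tp):
        proj = hw.project(ghana_census, ghana_tp, horizon=10)
        flows = hw.transition_flows(proj, ghana_tp)
        np.testing.assert_allclose(flows.totals.to_numpy(),
                                   flows.flows.sum(axis=0).to_numpy())
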