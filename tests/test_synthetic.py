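"""Synthetic generators: determinism, fixture values, microsimulation oracle."""
import numpy as np
import pandas as pd
import pytest

import hwforecast as hw
from hwforecast.categories import CATEGORIES, PAIRS


class TestFixture:
    def test_baseline_total(self, ghana_census):
        assert ghana_census.national(2016).sum() == 5749

    def test_primary_hospital_subtotal(self, ghana_census):
        assert sum(ghana_census.get("Ghana", c, 2016)
                   for c in ("PHA", "PHB", "PHC", "PHD")) == 188

    def test_transition_table_values(self, ghana_tp):
        assert ghana_tp.probability("RH", "EmTH") == pytest.approx(0.091)
        assert ghana_tp.standard_error("RH", "EmTH") == pytest.approx(0.003)
        assert ghana_tp.probability("CHPS", "HCA") == pytest.approx(0.010)


class TestPanelGenerator:
    def test_deterministic_under_seed(self):
        cfg = hw.GeneratorConfig(seed=3, years=3,
                                 n_facilities_per_category={"CHPS": 200, "PHA": 100})
        p1 = hw.simulate_panel(cfg).to_frame()
        p2 = hw.simulate_panel(cfg).to_frame()
        pd.testing.assert_frame_equal(p1, p2)
        p3 = hw.simulate_panel(hw.GeneratorConfig(
            seed=4, years=3,
            n_facilities_per_category={"CHPS": 200, "PHA": 100})).to_frame()
        assert not p1.equals(p3)

    def test_zero_probability_frozen(self):
        cfg = hw.GeneratorConfig(
            seed=1, years=4, n_facilities_per_category={"HCA": 100},
            tp_true=hw.TransitionTable(np.zeros(10), np.zeros(10)))
        counts = hw.panel_counts(hw.simulate_panel(cfg))
        assert (counts["HCA"] == 100).all()

    def test_certain_transition_moves_everyone(self):
        p = np.zeros(10)
        p[0] = 1.0
        cfg = hw.GeneratorConfig(
            seed=1, years=2, n_facilities_per_category={"CHPS": 50},
            tp_true=hw.TransitionTable(p, np.zeros(10)))
        counts = hw.panel_counts(hw.simulate_panel(cfg))
        assert counts.loc[2012, "HCA"] == 50 and counts.loc[2012, "CHPS"] == 0

    def test_no_downward_moves_ever(self):
        cfg = hw.GeneratorConfig(seed=9, years=5)
        df = hw.simulate_panel(cfg).records
        ranks = df.pivot(index="facility_id", columns="year", values="rank")
        assert (ranks.diff(axis=1).fillna(0) >= 0).all().all()

    def test_one_step_fractions_within_binomial_error(self):
        """Empirical one-step transition fractions track the truth at n=10,000."""
        n = 10_000
        cfg = hw.GeneratorConfig(seed=17, years=2,
                                 n_facilities_per_category={c: n for c in CATEGORIES})
        y0, y1 = cfg.panel_start_year, cfg.panel_start_year + 1
        df = hw.simulate_panel(cfg).records
        wide = df.pivot(index="facility_id", columns="year", values="rank")
        for r, (a, b) in enumerate(PAIRS):
            at_risk = (wide[y0] == r)
            frac = (wide.loc[at_risk, y1] == r + 1).mean()
            p = cfg.tp_true.p[r]
            tol = 3 * np.sqrt(max(p * (1 - p), 1e-12) / n) + 1e-9
            assert abs(frac - p) <= tol, (a, b)

    def test_censoring_drops_records(self):
        cfg = hw.GeneratorConfig(seed=2, years=4, missing_rate=0.3,
                                 n_facilities_per_category={"HCA": 500})
        df = hw.simulate_panel(cfg).records
        assert len(df) < 500 * 4


class TestMicrosimOracle:
    def test_expected_counts_match_deterministic_projection(self, ghana_tp):
        """Mean microsimulation censuses equal the cohort projection within MC error."""
        n = 2000
        years = 5
        reps = 20
        sums = np.zeros((years, len(CATEGORIES)))
        sq = np.zeros_like(sums)
        for rep in range(reps):
            cfg = hw.GeneratorConfig(
                seed=500 + rep, years=years, tp_true=ghana_tp,
                n_facilities_per_category={c: n for c in CATEGORIES})
            counts = hw.panel_counts(hw.simulate_panel(cfg)).to_numpy().astype(float)
            sums += counts
            sq += counts ** 2
        mean = sums / reps
        sd = np.sqrt(np.maximum(sq / reps - mean ** 2, 0.0))
        se = sd / np.sqrt(reps)

        baseline = hw.FacilityCensus.from_mapping(
            {("S", c, 0): float(n) for c in CATEGORIES}, baseline_year=0)
        proj = hw.project(baseline, ghana_tp, horizon=years - 1)
        expected = np.vstack([proj.national(y) for y in range(years)])
        # 3 MC standard errors, with a small absolute floor for near-degenerate cells
        assert (np.abs(mean - expected) <= 3 * se + 0.75).all()


class TestOtherGenerators:
    def test_norms_monotone_in_rank(self, norms):
        m = norms.standard.to_numpy()
        assert (np.diff(m, axis=1) >= -1e-12).all()
        assert m.shape == (23, 11)

    def test_norms_scale_doubles_requirements(self, ghana_census, gen_cfg):
        r1 = hw.compute_requirements(ghana_census, hw.synth_norms(gen_cfg))
        r2 = hw.compute_requirements(
            ghana_census,
            hw.synth_norms(hw.GeneratorConfig(seed=gen_cfg.seed, norms_scale=2.0)))
        np.testing.assert_allclose(r2.table["required"], 2 * r1.table["required"])

    def test_population_growth(self):
        cfg = hw.GeneratorConfig(seed=5, n_regions=2, pop_growth_rate=0.0)
        pop = hw.synth_population(cfg, n_years=4)
        for region in ("R01", "R02"):
            vals = [pop.get(region, 2016 + t) for t in range(4)]
            assert vals == pytest.approx([vals[0]] * 4)
        grow = hw.synth_population(hw.GeneratorConfig(seed=5, n_regions=1), n_years=3)
        assert grow.get("Ghana", 2018) == pytest.approx(
            grow.get("Ghana", 2016) * 1.022 ** 2)

    def test_roster_hits_sar_target(self, ghana_census, ghana_tp, gen_cfg, norms):
        req = hw.compute_requirements(ghana_census, norms)
        roster = hw.synth_roster(gen_cfg, req, year=2016)
        report = hw.sar_report(roster, req, 2016)
        agg = report.loc[report.staff_type == "ALL", "sar"].iloc[0]
        assert 0.63 <= agg <= 0.73

    def test_full_loop_recovery(self, ghana_census, ghana_tp, norms):
        """estimate -> project -> requirements reproduces the direct-truth pipeline."""
        cfg = hw.GeneratorConfig(
            seed=42, years=5, tp_true=ghana_tp,
            n_facilities_per_category={c: 4000 for c in CATEGORIES})
        tp_hat, _ = hw.estimate_transitions(hw.simulate_panel(cfg))
        req_hat = hw.compute_requirements(
            hw.project(ghana_census, tp_hat, horizon=5), norms)
        req_true = hw.compute_requirements(
            hw.project(ghana_census, ghana_tp, horizon=5), norms)
        for staff in ("Registered general nurse", "Medical officer (general practitioner)"):
            a = req_hat.national_value(staff, 2021)
            b = req_true.national_value(staff, 2021)
            assert a == pytest.approx(b, rel=0.10)
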