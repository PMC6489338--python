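"""Additive lifetime cancer risk, tiers, case accounting, contributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquarisk import (
    SystemProfile,
    TIER_LABELS,
    UnitMismatchError,
    annual_cases,
    classify_tier,
    contribution_by_group,
    cumulative_risk,
    lifetime_risk,
    per_system_table,
    tier_table,
    tier_table_frame,
)


def _profile(mean_conc, system_id="S1", population=1000):
    return SystemProfile(system_id=system_id, population=population,
                         mean_conc=mean_conc,
                         n_samples={c: 1 for c in mean_conc})


class TestLifetimeRisk:
    def test_arsenic_worked_example(self, arsenic):
        # 1 ug/L at the 0.004 ug/L one-in-a-million anchor
        assert lifetime_risk(1.0, arsenic.c_one_in_million) == pytest.approx(2.5e-4)

    def test_zero_concentration(self):
        assert lifetime_risk(0.0, 0.004) == 0.0

    def test_anchor_concentration_gives_one_in_a_million(self):
        assert lifetime_risk(0.004, 0.004) == pytest.approx(1e-6)

    def test_capped_at_one(self):
        assert lifetime_risk(1e12, 0.004) == 1.0

    def test_unit_mismatch_rejected(self):
        with pytest.raises(UnitMismatchError):
            lifetime_risk(1.0, 0.004, unit="mg/L", benchmark_unit="ug/L")

    @given(st.floats(0, 1e6, allow_nan=False), st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_linear_below_cap(self, conc, c1m):
        r = lifetime_risk(conc, c1m)
        if r < 1.0:
            assert lifetime_risk(2 * conc, c1m) == pytest.approx(
                min(2 * r, 1.0), rel=1e-12)


class TestCumulativeRisk:
    def test_two_contaminants_at_anchor_add(self, registry):
        profile = _profile({
            "arsenic": registry["arsenic"].c_one_in_million,
            "chloroform": registry["chloroform"].c_one_in_million,
        })
        result = cumulative_risk(profile, registry)
        assert result.cumulative_risk == pytest.approx(2e-6, rel=1e-12)

    def test_empty_profile(self, registry):
        result = cumulative_risk(_profile({}), registry)
        assert result.cumulative_risk == 0.0
        assert result.lifetime_cases == 0.0

    def test_noncancer_contaminants_do_not_contribute(self, registry):
        result = cumulative_risk(_profile({"nitrate": 5000.0}), registry)
        assert result.cumulative_risk == 0.0

    def test_matches_per_term_summation_oracle(self, registry):
        rng = np.random.default_rng(7)
        ids = ["arsenic", "chloroform", "uranium", "hexavalent_chromium",
               "tetrachloroethylene"]
        conc = {cid: float(rng.uniform(0, 5)) for cid in ids}
        result = cumulative_risk(_profile(conc, population=12345), registry)
        expected = sum(conc[c] / registry[c].c_one_in_million * 1e-6 for c in ids)
        assert result.cumulative_risk == pytest.approx(expected, rel=1e-12)
        assert result.lifetime_cases == pytest.approx(expected * 12345, rel=1e-12)
        assert sum(result.per_contaminant_risk.values()) == pytest.approx(
            result.cumulative_risk, rel=1e-12)

    def test_scaling_concentrations_scales_risk_linearly(self, registry):
        conc = {"arsenic": 1.0, "chloroform": 10.0}
        r1 = cumulative_risk(_profile(conc), registry).cumulative_risk
        r3 = cumulative_risk(
            _profile({c: 3 * v for c, v in conc.items()}), registry
        ).cumulative_risk
        assert r3 == pytest.approx(3 * r1, rel=1e-12)

    def test_adding_a_carcinogen_never_decreases_risk(self, registry):
        base = _profile({"arsenic": 1.0})
        more = _profile({"arsenic": 1.0, "uranium": 2.0})
        assert (cumulative_risk(more, registry).cumulative_risk
                >= cumulative_risk(base, registry).cumulative_risk)


class TestTiers:
    @pytest.mark.parametrize("risk,tier", [
        (2e-3, ">1e-3"),
        (1e-3, "1e-4–1e-3"),   # boundary: top tier is strictly > 1e-3
        (5e-4, "1e-4–1e-3"),
        (1e-4, "1e-5–1e-4"),
        (5e-5, "1e-5–1e-4"),
        (1e-5, "<1e-5"),
        (0.0, "<1e-5"),
    ])
    def test_boundaries_upper_inclusive(self, risk, tier):
        assert classify_tier(risk) == tier

    def test_rejects_risk_outside_unit_interval(self):
        with pytest.raises(ValueError):
            classify_tier(1.5)

    def test_four_rows_always_emitted(self, registry):
        results = [cumulative_risk(_profile({"arsenic": 10.0}), registry)]
        table = tier_table(results)
        assert [t.tier for t in table] == list(TIER_LABELS)
        assert sum(t.n_systems for t in table) == 1

    def test_single_system_takes_all_percent(self, registry):
        results = [cumulative_risk(_profile({"arsenic": 10.0}), registry)]
        table = tier_table(results)
        assert max(t.percent_of_total_cases for t in table) == pytest.approx(100.0)

    def test_published_style_top_tier_percent(self):
        # tier case counts 4860/10427/149/13 -> top tier 31% of the total
        from aquarisk.cancer import TierSummary
        cases = dict(zip(TIER_LABELS, [4860.0, 10427.0, 149.0, 13.0]))
        total = sum(cases.values())
        summaries = [
            TierSummary(tier=t, n_systems=1, exposed_population=1,
                        lifetime_cases=cases[t],
                        percent_of_total_cases=100 * cases[t] / total)
            for t in TIER_LABELS
        ]
        frame = tier_table_frame(summaries)
        assert frame.loc[0, "percent_of_total_cases"] == 31

    def test_zero_cases_gives_zero_percents(self, registry):
        results = [cumulative_risk(_profile({}, population=0), registry)]
        table = tier_table(results)
        assert all(t.percent_of_total_cases == 0.0 for t in table)

    def test_conservation_on_random_systems(self, registry):
        rng = np.random.default_rng(11)
        results = []
        for i in range(50):
            conc = {"arsenic": float(rng.lognormal(0, 2))}
            results.append(cumulative_risk(
                _profile(conc, system_id=f"S{i}",
                         population=int(rng.integers(10, 10_000))), registry))
        table = tier_table(results)
        assert sum(t.n_systems for t in table) == 50
        assert sum(t.exposed_population for t in table) == sum(
            r.population for r in results)
        assert sum(t.lifetime_cases for t in table) == pytest.approx(
            sum(r.lifetime_cases for r in results), rel=1e-12)
        assert sum(t.percent_of_total_cases for t in table) == pytest.approx(100.0)


class TestAnnualization:
    def test_published_arithmetic(self):
        # 15,449 lifetime cases over a 70-year lifetime -> 221 annual cases
        annual = annual_cases(15449, 70)
        assert annual == pytest.approx(220.7, abs=0.05)
        assert round(annual) == 221

    @pytest.mark.parametrize("cases,years,expected", [(0, 70, 0), (70, 70, 1)])
    def test_degenerate_inputs(self, cases, years, expected):
        assert annual_cases(cases, years) == expected

    def test_rejects_nonpositive_lifetime(self):
        with pytest.raises(ValueError):
            annual_cases(100, 0)


class TestGroupContributions:
    def test_single_contaminant_dataset_is_100_percent(self, registry):
        results = [cumulative_risk(_profile({"arsenic": 5.0}), registry)]
        shares = contribution_by_group(results, registry)
        assert shares == {"arsenic": pytest.approx(100.0)}

    def test_equal_cases_in_disjoint_groups_split_evenly(self, registry):
        a = cumulative_risk(_profile({"arsenic": 1.0}, "A", 1000), registry)
        b = cumulative_risk(
            _profile({"uranium": 2.5e-4 / 1e-6 * registry["uranium"].c_one_in_million},
                     "B", 1000), registry)
        shares = contribution_by_group([a, b], registry)
        assert shares["arsenic"] == pytest.approx(50.0, rel=1e-9)
        assert shares["radioactive"] == pytest.approx(50.0, rel=1e-9)

    def test_matches_direct_case_summation_oracle(self, registry):
        rng = np.random.default_rng(3)
        ids = [c.id for c in registry.carcinogens]
        results, oracle = [], {}
        for i in range(20):
            chosen = rng.choice(ids, size=3, replace=False)
            conc = {cid: float(rng.lognormal(0, 1) * registry[cid].c_one_in_million * 50)
                    for cid in chosen}
            pop = int(rng.integers(100, 100_000))
            results.append(cumulative_risk(_profile(conc, f"S{i}", pop), registry))
            for cid in chosen:
                g = registry[cid].group
                cases = conc[cid] / registry[cid].c_one_in_million * 1e-6 * pop
                oracle[g] = oracle.get(g, 0.0) + cases
        total = sum(oracle.values())
        shares = contribution_by_group(results, registry)
        for g, cases in oracle.items():
            assert shares[g] == pytest.approx(100 * cases / total, abs=1e-9)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_per_system_table_sorted_and_decomposed(self, registry):
        results = [
            cumulative_risk(_profile({"arsenic": 1.0}, "A"), registry),
            cumulative_risk(_profile({"arsenic": 8.0}, "B"), registry),
        ]
        table = per_system_table(results, registry)
        assert list(table.system_id) == ["B", "A"]
        assert table.risk_arsenic.tolist() == pytest.approx(
            table.cumulative_risk.tolist())
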