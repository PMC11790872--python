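"""Deterministic exposure chain: CDI arithmetic, HQ/HI/CR, survey fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coastrisk import defaults, health_risk as hr
from coastrisk.sample_io import Measurement, SampleRecord, SurveyTable


def scenario(**kw):
    base = dict(receptor="test", ir=2.0, ef=365.0, ed=30.0, bw=70.0,
                sa=18000.0, et=0.58, cf=0.001)
    base.update(kw)
    return hr.ExposureScenario(**base)


def metal_survey_of(values_per_sample):
    records = tuple(
        SampleRecord(
            str(i + 1), "x",
            {s: Measurement(float(vals.get(s, 0.0))) for s in defaults.METALS},
        )
        for i, vals in enumerate(values_per_sample)
    )
    return SurveyTable(records, "metals", "mg/L")


class TestCDI:
    def test_oral_direct_arithmetic(self):
        s = scenario(ir=2.0, ef=365.0, ed=30.0, bw=70.0, at=10950.0)
        # 1 * 2 * 365 * 30 / (70 * 10950)
        assert hr.cdi_oral(1.0, s) == pytest.approx(0.02857142857, rel=1e-9)

    def test_oral_zero_concentration(self):
        assert hr.cdi_oral(0.0, scenario()) == 0.0

    def test_oral_linearity(self):
        s = scenario()
        assert hr.cdi_oral(2.0, s) == pytest.approx(2 * hr.cdi_oral(1.0, s))

    def test_dermal_direct_arithmetic(self):
        s = scenario(et=0.58, ef=365.0, ed=30.0, bw=70.0, sa=18000.0,
                     cf=0.001, at=10950.0)
        # 1 * 0.58 * 365 * 0.001 * 18000 * 0.001 * 30 / (70 * 10950)
        assert hr.cdi_dermal(1.0, 0.001, s) == pytest.approx(1.49142857e-4, rel=1e-6)

    def test_dermal_zero_exposure_time(self):
        s = scenario(et=1e-12)
        assert hr.cdi_dermal(1.0, 0.001, s) == pytest.approx(0.0, abs=1e-15)

    def test_dermal_equals_oral_when_pathways_match(self):
        # kp * sa * cf * et == ir makes the two formulas congruent
        kp, sa, cf, et = 0.002, 10000.0, 0.001, 0.5
        s = scenario(ir=kp * sa * cf * et, sa=sa, cf=cf, et=et)
        assert hr.cdi_dermal(0.7, kp, s) == pytest.approx(
            hr.cdi_oral(0.7, s), rel=1e-12
        )

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario(bw=0.0)
        with pytest.raises(ValueError):
            scenario(at=-1.0)

    def test_at_defaults_to_ed_years(self):
        s = scenario(ed=30.0)
        assert s.at == 30.0 * 365.0


class TestHQ:
    def test_cdi_equal_rfd_gives_one(self):
        assert hr.hq(0.003, 0.003) == pytest.approx(1.0)

    def test_abs_one_makes_routes_agree(self):
        assert hr.hq(0.01, 0.003, abs_gi=1.0, route="dermal") == pytest.approx(
            hr.hq(0.01, 0.003, route="oral")
        )

    def test_halving_abs_doubles_dermal_hq(self):
        full = hr.hq(0.01, 0.003, abs_gi=1.0, route="dermal")
        half = hr.hq(0.01, 0.003, abs_gi=0.5, route="dermal")
        assert half == pytest.approx(2 * full)

    def test_zero_rfd_rejected(self):
        with pytest.raises(ValueError):
            hr.hq(0.01, 0.0)


class TestHIandCR:
    def test_hi_empty_is_zero(self):
        assert hr.hi({}) == 0.0

    def test_hi_sum_and_flag(self):
        assert hr.hi({"a": 0.5, "b": 0.5, "c": 0.1}) == pytest.approx(1.1)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=8))
    def test_hi_matches_loop_oracle_and_is_commutative(self, values):
        hqs = {f"m{i}": v for i, v in enumerate(values)}
        oracle = 0.0
        for v in values:
            oracle += v
        assert hr.hi(hqs) == pytest.approx(oracle, rel=1e-12)
        shuffled = dict(reversed(list(hqs.items())))
        assert hr.hi(shuffled) == pytest.approx(hr.hi(hqs), rel=1e-12)
        assert hr.hi(hqs) >= max(values) - 1e-12  # HI dominates any single HQ

    def test_cr_product_and_class(self):
        value = hr.cr(0.02857, 0.0085)
        assert value == pytest.approx(2.43e-4, rel=1e-2)
        assert hr.classify_cr(value) == "high"

    def test_cr_zero_slope(self):
        assert hr.cr(0.5, 0.0) == 0.0
        assert hr.classify_cr(0.0) == "negligible"

    def test_cr_monotone_in_cdi(self):
        assert hr.cr(0.2, 0.5) >= hr.cr(0.1, 0.5)


class TestSurveyRisk:
    def test_all_zero_survey_has_zero_fractions(self, registry):
        survey = metal_survey_of([{}, {}])
        _, fractions = hr.survey_risk(survey, registry)
        assert (fractions["frac_hq_gt_1"].dropna() == 0).all()
        assert (fractions["frac_cr_gt_1e4"].dropna() == 0).all()

    def test_single_sample_exceedance_is_100pct(self, registry):
        # Cd concentration chosen so adult oral HQ = 1.5
        scen = hr.default_scenarios()["adult"]
        c = 1.5 * registry.metals["Cd"].rfd_oral * scen.bw * scen.at / (
            scen.ir * scen.ef * scen.ed
        )
        _, fractions = hr.survey_risk(metal_survey_of([{"Cd": c}]), registry)
        row = fractions.query(
            "receptor == 'adult' and route == 'oral' and metal == 'Cd'"
        )
        assert row["frac_hq_gt_1"].iloc[0] == 1.0

    def test_fractions_match_per_sample_loop_oracle(self, registry):
        rng = np.random.default_rng(42)
        survey = metal_survey_of(
            [{s: float(rng.lognormal(-5, 1.5)) for s in defaults.METALS}
             for _ in range(12)]
        )
        results, fractions = hr.survey_risk(survey, registry)
        scen = hr.default_scenarios()
        for receptor in ("adult", "child"):
            for metal in defaults.METALS:
                ref = registry.metals[metal]
                count = 0
                s = scen[receptor]
                for rec in survey.records:  # independent scalar loop
                    dose = rec.value(metal) * s.ir * s.ef * s.ed / (s.bw * s.at)
                    if dose / ref.rfd_oral > 1.0:
                        count += 1
                row = fractions.query(
                    f"receptor == '{receptor}' and route == 'oral' "
                    f"and metal == '{metal}'"
                )
                assert row["frac_hq_gt_1"].iloc[0] == pytest.approx(count / 12)

    def test_hi_equals_sum_of_hqs(self, registry):
        rng = np.random.default_rng(7)
        survey = metal_survey_of(
            [{s: float(rng.lognormal(-4, 1)) for s in defaults.METALS}]
        )
        results, _ = hr.survey_risk(survey, registry)
        for r in results:
            assert r.hi_oral == pytest.approx(
                sum(rr["oral"].hq for rr in r.per_metal.values()), rel=1e-12
            )

    def test_cr_only_for_metals_with_slope_factor(self, metal_survey, registry):
        results, _ = hr.survey_risk(metal_survey, registry)
        with_csf = {m for m, ref in registry.metals.items() if ref.csf_oral}
        assert with_csf == {"Cd", "Cr", "Pb"}
        for r in results:
            for metal, per_route in r.per_metal.items():
                for route in hr.ROUTES:
                    assert (per_route[route].cr is not None) == (metal in with_csf)

    def test_child_risk_at_least_adult_per_metal(self, metal_survey, registry):
        """With the shipped scenarios the child's intake-per-body-weight
        exceeds the adult's, so child HQ and CR dominate for every metal."""
        results, _ = hr.survey_risk(metal_survey, registry)
        by_key = {(r.receptor, r.sample_id): r for r in results}
        for sid in (r.sample_id for r in results if r.receptor == "adult"):
            adult, child = by_key[("adult", sid)], by_key[("child", sid)]
            for metal in registry.metals:
                for route in hr.ROUTES:
                    a, c = adult.per_metal[metal][route], child.per_metal[metal][route]
                    assert c.hq >= a.hq
                    if a.cr is not None:
                        assert c.cr >= a.cr

    def test_chain_linear_in_concentration(self, registry):
        s1 = metal_survey_of([{"Pb": 0.1}])
        s2 = metal_survey_of([{"Pb": 0.3}])
        r1, _ = hr.survey_risk(s1, registry)
        r2, _ = hr.survey_risk(s2, registry)
        for a, b in zip(r1, r2):
            assert b.per_metal["Pb"]["oral"].hq == pytest.approx(
                3 * a.per_metal["Pb"]["oral"].hq, rel=1e-12
            )
            assert b.per_metal["Pb"]["dermal"].cr == pytest.approx(
                3 * a.per_metal["Pb"]["dermal"].cr, rel=1e-12
            )
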