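"""PAH aggregation, diagnostic ratios, risk quotients, and TOC summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coastrisk import defaults, pah_metrics as pm
from coastrisk.sample_io import (
    Measurement,
    SampleRecord,
    SurveySchemaError,
    SurveyTable,
)


def make_pah_sample(values: dict, sample_id="T1") -> SampleRecord:
    """A full 16-compound PAH sample; unspecified compounds are 0."""
    return SampleRecord(
        sample_id,
        "test",
        {ab: Measurement(float(values.get(ab, 0.0))) for ab in defaults.PAHS},
    )


concentrations = st.lists(
    st.floats(0.0, 1e3, allow_nan=False, allow_infinity=False),
    min_size=16, max_size=16,
)


class TestTotals:
    def test_suez_total_is_printed_479(self, pah_survey, registry):
        assert pm.total_pahs(pah_survey.records[0], registry) == pytest.approx(
            479.02, abs=1e-9
        )

    def test_all_nd_sample_sums_to_zero(self, registry):
        assert pm.total_pahs(make_pah_sample({}), registry) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(concentrations)
    def test_total_matches_accumulation_oracle(self, registry, values):
        sample = make_pah_sample(dict(zip(defaults.PAHS, values)))
        oracle = 0.0
        for ab in defaults.PAHS:  # independent plain accumulation
            oracle += sample.value(ab)
        assert pm.total_pahs(sample, registry) == pytest.approx(oracle, rel=1e-12)

    def test_missing_compound_is_named(self, registry):
        partial = SampleRecord("x", "x", {"Naph": Measurement(1.0)})
        with pytest.raises(SurveySchemaError, match="Phe"):
            pm.total_pahs(partial, registry)


class TestGroupTotals:
    def test_suez_car_is_sum_of_its_three_detected_members(self, pah_survey, registry):
        s = pm.group_totals(pah_survey.records[0], registry)
        assert s.car_total == pytest.approx(2.12 + 8.04 + 19.46)

    def test_suez_lpah(self, pah_survey, registry):
        s = pm.group_totals(pah_survey.records[0], registry)
        assert s.lpah_total == pytest.approx(6.40, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(concentrations)
    def test_lpah_hpah_partition_total(self, registry, values):
        sample = make_pah_sample(dict(zip(defaults.PAHS, values)))
        s = pm.group_totals(sample, registry)
        assert s.lpah_total + s.hpah_total == pytest.approx(s.total, rel=1e-9)
        assert 0.0 <= s.car_total <= s.total + 1e-9


class TestDiagnosticRatios:
    def test_qusier_baa_ratio(self, pah_survey, registry):
        r = pm.diagnostic_ratios(pah_survey.records[7], registry)
        assert r.baa_baachry == pytest.approx(0.173 / (0.173 + 0.346))
        assert r.baa_baachry == pytest.approx(0.333, abs=5e-4)

    def test_ain_sukhna_phe_ant(self, pah_survey, registry):
        r = pm.diagnostic_ratios(pah_survey.records[1], registry)
        assert r.phe_ant == pytest.approx(5.406, rel=0.01)

    def test_zero_denominator_is_undefined_not_zero(self, registry):
        sample = make_pah_sample({"Phe": 1.0, "Ant": 0.0, "Flu": 1.0, "Pyr": 2.0})
        r = pm.diagnostic_ratios(sample, registry)
        assert r.phe_ant is None
        assert r.flu_pyr == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(concentrations, st.floats(0.1, 100.0))
    def test_scale_equivariance(self, registry, values, k):
        """Scaling all concentrations by k scales totals and RQs by k but
        leaves every diagnostic ratio and source label unchanged."""
        a = make_pah_sample(dict(zip(defaults.PAHS, values)))
        b = make_pah_sample({ab: k * a.value(ab) for ab in defaults.PAHS})
        assert pm.total_pahs(b, registry) == pytest.approx(
            k * pm.total_pahs(a, registry), rel=1e-9
        )
        ra, rb = pm.diagnostic_ratios(a, registry), pm.diagnostic_ratios(b, registry)
        for name in ("lmw_hmw", "phe_ant", "flu_pyr", "flu_flupyr", "baa_baachry"):
            va, vb = getattr(ra, name), getattr(rb, name)
            assert (va is None) == (vb is None)
            if va is not None:
                assert vb == pytest.approx(va, rel=1e-9)
        assert pm.classify_source(ra) == pm.classify_source(rb)
        qa, qb = pm.site_total_rq(a, registry), pm.site_total_rq(b, registry)
        assert qb.rq_nc == pytest.approx(k * qa.rq_nc, rel=1e-9)


class TestSourceClassification:
    def test_all_sites_pyrogenic_by_lmw_hmw(self, pah_survey, registry):
        for sample in pah_survey.records:
            labels = pm.classify_source(pm.diagnostic_ratios(sample, registry))
            assert labels["lmw_hmw"] == "pyrogenic"

    def test_all_sites_petroleum_by_flu_flupyr(self, pah_survey, registry):
        for sample in pah_survey.records:
            r = pm.diagnostic_ratios(sample, registry)
            assert r.flu_flupyr < 0.4
            assert pm.classify_source(r)["flu_flupyr"] == "petrogenic"

    def test_boundary_goes_to_upper_class(self, registry):
        # Flu/(Flu+Pyr) exactly 0.4 -> mixed band, exactly 0.5 -> combustion
        at_04 = pm.DiagnosticRatios(None, None, None, 0.4, None)
        at_05 = pm.DiagnosticRatios(None, None, None, 0.5, None)
        assert pm.classify_source(at_04)["flu_flupyr"] == "mixed/ambiguous"
        assert pm.classify_source(at_05)["flu_flupyr"] == "pyrogenic"

    def test_undefined_ratios_do_not_vote(self):
        only_one = pm.DiagnosticRatios(0.5, None, None, None, None)
        labels = pm.classify_source(only_one)
        assert labels["phe_ant"] == "undefined"
        assert labels["consensus"] == "pyrogenic"


class TestRiskQuotients:
    def test_ain_sukhna_naph_rq(self, pah_survey, registry):
        out = pm.rq(pah_survey.records[1], registry)
        assert out["Naph"].rq_nc == pytest.approx(70.0)  # 0.084 ug/L vs 1.2 ng/L
        assert out["Naph"].rq_mpc == pytest.approx(0.07)

    def test_concentration_equal_to_nc_gives_rq_one(self, registry):
        nc_ug = registry.pahs["BaP"].nc / 1000.0
        sample = make_pah_sample({"BaP": nc_ug})
        assert pm.rq(sample, registry)["BaP"].rq_nc == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(concentrations)
    def test_rq_matches_scalar_loop_oracle(self, registry, values):
        sample = make_pah_sample(dict(zip(defaults.PAHS, values)))
        out = pm.rq(sample, registry)
        for ab in defaults.PAHS:
            ref = registry.pahs[ab]
            assert out[ab].rq_nc == sample.value(ab) * 1000.0 / ref.nc
            assert out[ab].rq_mpc == sample.value(ab) * 1000.0 / ref.mpc
            assert out[ab].rq_nc >= out[ab].rq_mpc  # since MPC >= NC

    def test_site_total_uses_total_row_quality_values(self, pah_survey, registry):
        tot = pm.site_total_rq(pah_survey.records[0], registry)
        assert tot.rq_nc == pytest.approx(479.02 * 1000 / 27.2)


class TestGrading:
    @pytest.mark.parametrize(
        "rq_nc,rq_mpc,expected",
        [
            (982.7, 9.8, "high"),  # Zaafarana N. site total
            (723.7, 7.2, "moderate"),  # Ain Sukhna site total
            (800.0, 1.0, "high"),  # boundary belongs to high
            (10.0, 0.5, "low"),
            (0.5, 0.001, "negligible"),
        ],
    )
    def test_grade_rule_table(self, rq_nc, rq_mpc, expected):
        assert pm.grade_rq(pm.RQResult(rq_nc, rq_mpc)) == expected

    @settings(max_examples=50, deadline=None)
    @given(concentrations, st.integers(0, 15), st.floats(1.0, 10.0))
    def test_grade_monotone_in_concentration(self, registry, values, idx, bump):
        order = ["negligible", "low", "moderate", "high"]
        a = make_pah_sample(dict(zip(defaults.PAHS, values)))
        raised = dict(zip(defaults.PAHS, values))
        raised[defaults.PAHS[idx]] = raised[defaults.PAHS[idx]] + bump
        b = make_pah_sample(raised)
        ga = pm.grade_rq(pm.site_total_rq(a, registry))
        gb = pm.grade_rq(pm.site_total_rq(b, registry))
        assert order.index(gb) >= order.index(ga)


class TestTOC:
    def test_fixture_summary(self, toc_survey):
        s = pm.toc_summary(toc_survey)
        assert s["mean"] == pytest.approx(1.671, rel=1e-3)
        assert s["max"] == 2.31
        assert s["min"] == 1.52

    def test_single_record(self):
        rec = SampleRecord("1", "x", {"TOC": Measurement(1.5)})
        s = pm.toc_summary(SurveyTable((rec,), "toc", "mg/L"))
        assert s["mean"] == s["min"] == s["max"] == 1.5

    def test_order_property_and_empty_error(self, toc_survey):
        s = pm.toc_summary(toc_survey)
        assert s["min"] <= s["mean"] <= s["max"]
        with pytest.raises(ValueError):
            pm.toc_summary(SurveyTable((), "toc", "mg/L"))
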