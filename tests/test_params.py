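import json
import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import drscreen as d
from drscreen.params import ParameterSpec, registry_frame


class TestRateConversion:
    @pytest.mark.parametrize("p,t,expected", [
        (0.0, 5.0, 0.0),
        (0.5, 1.0, math.log(2)),
    ])
    def test_known_values(self, p, t, expected):
        assert d.annual_rate_from_cumulative(p, t) == pytest.approx(expected, abs=1e-12)

    def test_matches_root_finding_inversion(self):
        # independent oracle: solve 1 - exp(-5 r) = 0.18 numerically
        r_oracle = brentq(lambda r: 1 - math.exp(-5 * r) - 0.18, 0.0, 1.0,
                          xtol=1e-14)
        assert d.annual_rate_from_cumulative(0.18, 5.0) == pytest.approx(
            r_oracle, abs=1e-12)

    @pytest.mark.parametrize("r,t,expected", [
        (0.0, 1.0, 0.0),
        (math.log(2), 1.0, 0.5),
    ])
    def test_inverse_known_values(self, r, t, expected):
        assert d.probability_from_rate(r, t) == pytest.approx(expected, abs=1e-12)

    @given(p=st.floats(0.0, 0.999), t=st.floats(0.01, 50.0))
    def test_round_trip_identity(self, p, t):
        r = d.annual_rate_from_cumulative(p, t)
        assert d.probability_from_rate(r, t) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p,t", [(1.0, 1.0), (-0.1, 1.0), (0.5, 0.0), (0.5, -2)])
    def test_domain_errors(self, p, t):
        with pytest.raises(ValueError):
            d.annual_rate_from_cumulative(p, t)
        with pytest.raises(ValueError):
            d.probability_from_rate(-0.5, 1.0)


class TestLoading:
    def test_default_config_loads_printed_values(self, default_model):
        params, strategies = default_model
        assert params.discount_rate == 0.035
        assert params.values["u_blind"] == 0.55
        assert params.values["u_no_dr"] == 0.87
        assert params.gdp_per_capita == 22600.0
        assert strategies["ai"].sensitivity == 0.8047
        assert strategies["ai"].specificity == 0.9796
        assert strategies["manual"].sensitivity == 1.0
        assert strategies["ai"].screening_cost_per_attendee == 9.60
        assert strategies["manual"].screening_cost_per_attendee == 10.10
        assert strategies["ai"].compliance_referral == 0.504

    def test_printed_values_are_paper_text_provenance(self, default_model):
        params, _ = default_model
        printed = {
            "u_no_dr", "u_non_stdr", "u_stdr", "u_blind",
            "sens_ai", "spec_ai", "compliance_referral",
            "compliance_multiplier_ai", "cost_screening_manual",
            "cost_screening_ai", "cost_blind_first_year",
            "share_blind_direct_medical", "share_blind_direct_nonmedical",
            "share_blind_indirect",
        }
        for name in printed:
            assert params.specs[name].provenance == "paper-text", name
        others = set(params.specs) - printed
        assert all(params.specs[n].provenance == "supplement-placeholder"
                   for n in others)

    def test_shipped_json_matches_programmatic_default(self):
        shipped = json.loads(
            (Path(__file__).parent.parent / "src" / "drscreen" / "data"
             / "default_config.json").read_text())
        assert shipped == d.default_config()

    def test_utility_bound_violation_rejected(self):
        cfg = d.default_config()
        for e in cfg["parameters"]:
            if e["name"] == "u_blind":
                e["base"] = e["high"] = 1.2
        with pytest.raises(d.ValidationError, match="u_blind"):
            d.load_parameters(cfg)

    def test_all_failures_reported_at_once(self):
        cfg = d.default_config()
        bad = {"u_blind": 1.2, "cost_screening_ai": -5.0}
        for e in cfg["parameters"]:
            if e["name"] in bad:
                e["base"] = bad[e["name"]]
                e["low"] = min(e["low"], e["base"])
                e["high"] = max(e["high"], e["base"])
        with pytest.raises(d.ValidationError) as exc:
            d.load_parameters(cfg)
        msgs = "\n".join(exc.value.errors)
        assert "u_blind" in msgs and "cost_screening_ai" in msgs

    def test_range_inversion_rejected(self):
        cfg = d.default_config()
        cfg["parameters"][0]["low"] = cfg["parameters"][0]["high"] + 0.1
        with pytest.raises(d.ValidationError, match="range inversion"):
            d.load_parameters(cfg)

    def test_missing_parameter_rejected(self):
        cfg = d.default_config()
        cfg["parameters"] = [e for e in cfg["parameters"]
                             if e["name"] != "compliance_referral"]
        with pytest.raises(d.ValidationError, match="compliance_referral"):
            d.load_parameters(cfg)

    def test_degenerate_point_ranges_load(self):
        cfg = d.default_config()
        for e in cfg["parameters"]:
            e["low"] = e["high"] = e["base"]
        params, _ = d.load_parameters(cfg)
        assert all(s.low == s.high == s.base for s in params.specs.values())

    def test_unknown_override_rejected(self):
        with pytest.raises(d.ValidationError, match="unknown parameter"):
            d.load_parameters(overrides={"no_such_knob": 1.0})

    def test_cny_entered_cost_converted_at_load(self):
        cfg = d.default_config()
        for e in cfg["parameters"]:
            if e["name"] == "cost_referral_exam":
                e["base"], e["low"], e["high"] = 690.0, 345.0, 1035.0
                e["units"] = "CNY"
        params, _ = d.load_parameters(cfg)
        spec = params.specs["cost_referral_exam"]
        assert spec.base == pytest.approx(100.0)
        assert spec.units == "USD"

    def test_initial_distribution_is_simplex(self, default_model):
        params, _ = default_model
        assert params.initial_distribution.sum() == pytest.approx(1.0, abs=1e-12)
        assert params.initial_distribution.min() >= 0


def test_registry_frame_columns():
    frame = registry_frame()
    assert list(frame.columns) == ["name", "base", "low", "high", "dist",
                                   "units", "provenance"]
    assert frame["name"].is_unique


def test_spec_family_support_validation():
    assert ParameterSpec("x", 1.5, 1.0, 2.0, "beta").validate()
    assert ParameterSpec("x", -1.0, -2.0, 0.0, "gamma").validate()
    assert not ParameterSpec("x", 0.5, 0.4, 0.6, "beta").validate()
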