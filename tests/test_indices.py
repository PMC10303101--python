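import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autocmap.indices import (
    default_toxicity_weights,
    fatty_liver_index,
    flag_out_of_reference,
    fli_category,
    framingham_risk,
    mets_atpiii,
    obesity_flag,
    progetto_cuore_risk,
    toxicity_index,
    vai_reference_cutoff,
    visceral_adiposity_index,
)
from autocmap.schema import TOXIC_SYMBOLS

# Table-2 median hair concentrations of the 13 toxic elements, μg/g
_TOXIC_MEDIANS = {
    "Al": 4.10, "Sb": 0.02, "As": 0.03, "Ba": 0.95, "Bi": 0.02, "Cd": 0.03,
    "Pb": 0.59, "Hg": 1.20, "U": 0.07, "Ni": 0.30, "Ag": 0.21, "Sn": 0.28,
    "Ti": 0.59,
}


class TestFattyLiverIndex:
    def test_matches_independent_logistic_oracle(self):
        # single-expression evaluation of the Bedogni logistic formula
        tg, bmi, ggt, wc = 98.0, 32.1, 30.0, 97.0
        lin = (0.953 * math.log(tg) + 0.139 * bmi + 0.718 * math.log(ggt)
               + 0.053 * wc - 15.745)
        oracle = 100.0 * math.exp(lin) / (1.0 + math.exp(lin))
        assert fatty_liver_index(tg, bmi, ggt, wc) == pytest.approx(oracle, abs=1e-12)

    def test_low_inputs_exclude_fatty_liver(self):
        fli = fatty_liver_index(43, 18, 5, 60)
        assert fli < 30
        assert fli_category(fli) == "fatty liver excluded"

    @given(tg=st.floats(40, 300), bmi=st.floats(18, 55),
           ggt=st.floats(5, 300), wc=st.floats(60, 140))
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_0_100(self, tg, bmi, ggt, wc):
        assert 0.0 <= fatty_liver_index(tg, bmi, ggt, wc) <= 100.0

    def test_monotone_in_each_argument(self):
        base = fatty_liver_index(100, 30, 40, 95)
        assert fatty_liver_index(150, 30, 40, 95) > base
        assert fatty_liver_index(100, 35, 40, 95) > base
        assert fatty_liver_index(100, 30, 60, 95) > base
        assert fatty_liver_index(100, 30, 40, 110) > base

    def test_non_positive_input_raises(self):
        with pytest.raises(ValueError):
            fatty_liver_index(0, 30, 40, 95)


class TestVisceralAdiposityIndex:
    def test_male_unit_construction_gives_one(self):
        bmi = 30.0
        assert visceral_adiposity_index(
            "male", 39.68 + 1.88 * bmi, bmi, 1.03, 1.31
        ) == pytest.approx(1.0, abs=1e-12)

    def test_female_matches_independent_oracle(self):
        wc, bmi, tg, hdl = 99.0, 32.7, 1.24, 1.35
        oracle = (wc / (36.58 + 1.89 * bmi)) * (tg / 0.81) * (1.52 / hdl)
        assert visceral_adiposity_index("female", wc, bmi, tg, hdl) == \
            pytest.approx(oracle, abs=1e-12)

    def test_linear_in_tg(self):
        a = visceral_adiposity_index("female", 99, 32.7, 1.0, 1.35)
        b = visceral_adiposity_index("female", 99, 32.7, 2.0, 1.35)
        assert b / a == pytest.approx(2.0, abs=1e-12)

    def test_mgdl_units_guard(self):
        with pytest.raises(ValueError, match="mg/dL"):
            visceral_adiposity_index("male", 99, 32.7, 109.0, 1.35)


class TestVaiCutoff:
    @pytest.mark.parametrize("age,cutoff", [
        (35, 2.23), (30, 2.23), (41, 2.23), (42, 1.92), (51, 1.92),
        (52, 1.93), (65, 1.93), (66, 2.0), (80, 2.0),
    ])
    def test_printed_bands(self, age, cutoff):
        assert vai_reference_cutoff(age) == cutoff

    def test_undefined_below_30(self):
        with pytest.raises(ValueError):
            vai_reference_cutoff(29)


class TestFramingham:
    def test_table_floor_for_protective_profile(self):
        # youngest band, high HDL, low TC/SBP, no smoking: -9 (age) - 1 (HDL)
        points, risk = framingham_risk(30, "male", 150, 65, 110, False, False)
        assert points == -10
        assert risk == 0.5  # below the "<1%" table floor

    def test_mid_table_hand_summation(self):
        # male 56y: age 8; TC 220 @50-59: 3; smoker @50-59: 3; HDL 45: 1;
        # SBP 145 untreated: 1 → 16 points → 25% ten-year risk
        points, risk = framingham_risk(56, "male", 220, 45, 145, False, True)
        assert points == 8 + 3 + 3 + 1 + 1
        assert risk == 25.0

    def test_female_mid_table(self):
        # female 63y: age 10; TC 250 @60-69: 3; non-smoker; HDL 52: 0;
        # SBP 135 treated: 4 → 17 points → 5%
        points, risk = framingham_risk(63, "female", 250, 52, 135, True, False)
        assert points == 17
        assert risk == 5.0

    def test_raising_sbp_band_never_lowers_points(self):
        prev = -99
        for sbp in (110, 125, 135, 150, 165):
            pts, _ = framingham_risk(50, "female", 200, 50, sbp, False, False)
            assert pts >= prev
            prev = pts

    def test_out_of_range_age(self):
        with pytest.raises(ValueError):
            framingham_risk(85, "male", 200, 50, 120, False, False)


class TestMetS:
    BASE = dict(wc=80, sex="male", tg=100, hdl=55, sbp=118, dbp=75,
                bp_treated=False, glucose=90)

    def test_all_components_normal(self):
        assert mets_atpiii(**self.BASE) is False

    def test_exactly_three_abnormal(self):
        args = dict(self.BASE, wc=110, tg=180, glucose=110)
        assert mets_atpiii(**args) is True

    def test_exactly_two_abnormal(self):
        args = dict(self.BASE, wc=110, tg=180)
        assert mets_atpiii(**args) is False

    def test_treated_bp_counts_as_component(self):
        args = dict(self.BASE, bp_treated=True, tg=160, hdl=35)
        assert mets_atpiii(**args) is True

    def test_sex_specific_wc_threshold(self):
        assert mets_atpiii(90, "female", 160, 45, 132, 86, False, 90) is True
        assert mets_atpiii(90, "male", 160, 45, 132, 86, False, 90) is False

    def test_missing_component_raises(self):
        with pytest.raises(ValueError, match="missing"):
            mets_atpiii(90, "male", float("nan"), 45, 132, 86, False, 90)


class TestObesity:
    @pytest.mark.parametrize("bmi,flag", [(30.0, False), (30.1, True), (54.7, True)])
    def test_strict_threshold(self, bmi, flag):
        assert obesity_flag(bmi) is flag


class TestToxicityIndex:
    def test_zero_concentrations_give_zero(self):
        assert toxicity_index({s: 0.0 for s in TOXIC_SYMBOLS}) == 0.0

    def test_single_nonzero_element_definition(self):
        conc = {s: 0.0 for s in TOXIC_SYMBOLS}
        conc["Hg"] = 2.0
        w = default_toxicity_weights()
        expected = 2.0 * w["Hg"] / sum(w.values())
        assert toxicity_index(conc) == pytest.approx(expected, abs=1e-12)

    def test_equal_weights_on_medians_is_arithmetic_mean(self):
        # hand computation from the published per-element medians
        expected = sum(_TOXIC_MEDIANS.values()) / 13
        w = {s: 1.0 for s in TOXIC_SYMBOLS}
        assert toxicity_index(_TOXIC_MEDIANS, w) == pytest.approx(expected, abs=1e-12)

    @given(k=st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_in_concentrations(self, k):
        base = toxicity_index(_TOXIC_MEDIANS)
        scaled = toxicity_index({s: k * c for s, c in _TOXIC_MEDIANS.items()})
        assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-12)

    def test_weight_scale_invariance(self):
        w = default_toxicity_weights()
        w10 = {s: 10.0 * x for s, x in w.items()}
        assert toxicity_index(_TOXIC_MEDIANS, w) == pytest.approx(
            toxicity_index(_TOXIC_MEDIANS, w10), abs=1e-12)

    def test_negative_concentration_and_missing_element_raise(self):
        bad = dict(_TOXIC_MEDIANS, Hg=-1.0)
        with pytest.raises(ValueError, match="negative"):
            toxicity_index(bad)
        partial = {s: 1.0 for s in list(TOXIC_SYMBOLS)[:-1]}
        with pytest.raises(ValueError, match="missing"):
            toxicity_index(partial)


class TestReferenceFlags:
    @pytest.mark.parametrize("symbol,value,flag", [
        ("Ba", 1.29, "high"), ("Zn", 176.6, "normal"), ("Sr", 9.70, "high"),
        ("Co", 0.002, "low"), ("Hg", 0.39, "normal"),
    ])
    def test_published_examples(self, symbol, value, flag):
        assert flag_out_of_reference({symbol: value})[symbol] == flag

    def test_toxic_elements_never_low(self, rng):
        conc = {s: float(v) for s, v in
                zip(TOXIC_SYMBOLS, rng.uniform(0, 5, len(TOXIC_SYMBOLS)))}
        assert "low" not in flag_out_of_reference(conc).values()

    def test_unknown_symbol_raises(self):
        with pytest.raises(KeyError):
            flag_out_of_reference({"Xx": 1.0})


def test_progetto_cuore_is_a_stub():
    with pytest.raises(NotImplementedError):
        progetto_cuore_risk(age=50)
    assert progetto_cuore_risk(3, chart=lambda x: 2.0 * x) == 6.0
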