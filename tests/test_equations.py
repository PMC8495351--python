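"""Closed-form equation oracles and algebraic properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmintake.equations import (
    LAG2,
    LAG3,
    KFSD_COEFFICIENTS,
    CowState,
    DietComposition,
    LagSpec,
    ModelCoefficients,
    fcm_4pct,
    lag_multiplier,
    metabolic_bw,
    predict_batch,
    predict_cncps,
    predict_jfs,
    predict_kfsd,
    predict_nrc,
)
from dmintake.errors import (
    ConfigurationError,
    InvalidInputError,
    MissingPredictorError,
)


class TestFcm:
    @pytest.mark.parametrize("my,fat,expected", [
        (30.0, 4.0, 30.0),            # identity at 4% fat
        (0.0, 3.5, 0.0),
        (33.89, 3.60, 31.8566),       # hand arithmetic 0.4*33.89 + 15*0.036*33.89
    ])
    def test_values(self, my, fat, expected):
        assert fcm_4pct(my, fat) == pytest.approx(expected, abs=1e-4)

    def test_linear_in_milk_yield(self):
        assert fcm_4pct(20, 3.5) * 2 == pytest.approx(fcm_4pct(40, 3.5))

    @pytest.mark.parametrize("my,fat", [(-1, 4.0), (30, 0.0), (30, -2.0), (30, 15.0)])
    def test_invalid_inputs(self, my, fat):
        with pytest.raises(InvalidInputError):
            fcm_4pct(my, fat)


class TestMetabolicBW:
    @pytest.mark.parametrize("bw,expected", [
        (1.0, 1.0),
        (16.0, 8.0),                       # 16^0.75 = 2^3
        (640.0, 127.2433166),              # exp(0.75*ln 640)
    ])
    def test_values(self, bw, expected):
        assert metabolic_bw(bw) == pytest.approx(expected, rel=1e-8)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            metabolic_bw(0.0)


class TestLag:
    @pytest.mark.parametrize("spec,wol,expected", [
        (LAG2, 4.0, 0.8660),               # 1 - exp(-0.316*6.36)
        (LAG3, 20.0, 0.9894),              # 1 - exp(-0.192*23.67)
    ])
    def test_values(self, spec, wol, expected):
        assert lag_multiplier(spec, wol) == pytest.approx(expected, abs=2e-4)

    def test_limit_is_one(self):
        assert lag_multiplier(LAG2, 1e6) == pytest.approx(1.0)

    @given(st.floats(min_value=1, max_value=59))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_and_bounded(self, wol):
        for spec in (LAG2, LAG3):
            m = lag_multiplier(spec, wol)
            assert 0 < m < 1
            assert lag_multiplier(spec, wol + 0.5) > m

    def test_lag_converges_by_week_60(self):
        cow = CowState(bw=640, fcm=31.2, wol=60)
        diet = DietComposition(ndf_pct=33.4)
        with_lag = predict_kfsd(cow, diet, apply_lag=True)
        without = predict_kfsd(cow, diet, apply_lag=False)
        assert abs(with_lag - without) < 1e-6

    def test_invalid_spec_and_wol(self):
        with pytest.raises(InvalidInputError):
            LagSpec(rate=-1, offset=2.0)
        with pytest.raises(InvalidInputError):
            lag_multiplier(LAG2, 0.5)


class TestPredictions:
    def test_kfsd_printed_coefficients(self):
        cow = CowState(bw=640, fcm=31.2, wol=20)
        assert cow.mbw == pytest.approx(127.2433, abs=1e-3)
        diet = DietComposition(ndf_pct=33.4)
        # 4.103 + 0.112*127.2433 + 0.284*31.2 - 0.119*33.4
        assert predict_kfsd(cow, diet) == pytest.approx(23.2405, abs=2e-3)

    def test_kfsd_degenerate_coefficients(self):
        coef = ModelCoefficients(intercept=4.103, b_mbw=0, b_fcm=0, b_ndf=0)
        cow = CowState(bw=640, fcm=31.2, wol=5)
        assert predict_kfsd(cow, DietComposition(ndf_pct=33.4), coef=coef) == 4.103

    def test_nrc_values(self):
        cow = CowState(bw=640, fcm=32.0, wol=20)
        assert predict_nrc(cow, lag=LAG3) == pytest.approx(23.9638, abs=2e-3)
        assert predict_nrc(cow, lag=None) == pytest.approx(24.2217, abs=2e-3)

    def test_cncps_values(self):
        cow = CowState(bw=640, fcm=32.0, wol=4)
        assert predict_cncps(cow, lag=None) == pytest.approx(21.60, abs=1e-6)
        assert predict_cncps(cow, lag=LAG2) == pytest.approx(21.60 * 0.86598, abs=2e-3)

    def test_jfs_values(self):
        base = CowState(bw=1.0, fcm=0.0, wol=10, parity="multiparous")
        assert predict_jfs(base) == pytest.approx(1.3922 + 0.05839, abs=1e-6)
        mult = CowState(bw=640, fcm=32.0, wol=1e6, parity="multiparous")
        # limit: 1.3922 + 0.05839*640^0.75 + 0.40497*32
        assert predict_jfs(mult) == pytest.approx(21.7810, abs=2e-3)
        prim = CowState(bw=640, fcm=32.0, wol=1e6, parity="primiparous")
        # limit: 1.9120 + 0.07031*640^0.75 + 0.34923*32*1.3671
        assert predict_jfs(prim) == pytest.approx(26.1363, abs=2e-3)

    def test_missing_predictor_names_field(self):
        cow = CowState(bw=640, wol=4)  # no fcm
        with pytest.raises(MissingPredictorError) as err:
            predict_kfsd(cow, DietComposition(ndf_pct=33.4))
        assert err.value.field == "fcm"
        with pytest.raises(MissingPredictorError) as err:
            predict_kfsd(CowState(bw=640, fcm=30.0, wol=4), DietComposition())
        assert err.value.field == "ndf_pct"

    def test_negative_prediction_clamps_with_warning(self):
        coef = ModelCoefficients(intercept=-50.0, b_mbw=0, b_fcm=0, b_ndf=0)
        cow = CowState(bw=640, fcm=31.2, wol=5)
        with pytest.warns(RuntimeWarning):
            out = predict_kfsd(cow, DietComposition(ndf_pct=33.4), coef=coef)
        assert out == 0.0

    def test_coefficient_homogeneity(self, rng):
        """Doubling all coefficients doubles the no-lag prediction (linearity)."""
        c = KFSD_COEFFICIENTS
        doubled = ModelCoefficients(intercept=2 * c.intercept, b_mbw=2 * c.b_mbw,
                                    b_fcm=2 * c.b_fcm, b_ndf=2 * c.b_ndf)
        for _ in range(1000):
            cow = CowState(bw=rng.uniform(400, 850), fcm=rng.uniform(10, 50),
                           wol=rng.uniform(1, 44))
            diet = DietComposition(ndf_pct=rng.uniform(25, 60))
            one = predict_kfsd(cow, diet)
            two = predict_kfsd(cow, diet, coef=doubled)
            assert two == pytest.approx(2 * one, rel=1e-12)


class TestBatch:
    def test_empty(self):
        preds, notes = predict_batch([], "kfsd")
        assert preds == [] and notes == []

    def test_unknown_model(self):
        with pytest.raises(ConfigurationError):
            predict_batch([], "mystery")

    def test_batch_equals_scalar_bit_for_bit(self, rng):
        records = [
            (CowState(bw=rng.uniform(400, 850), fcm=rng.uniform(10, 50),
                      wol=rng.uniform(1, 44),
                      parity="multiparous" if rng.random() < 0.7 else "primiparous"),
             DietComposition(ndf_pct=rng.uniform(25, 60)))
            for _ in range(100)
        ]
        for name, fn in [
            ("kfsd", lambda c, d: predict_kfsd(c, d)),
            ("nrc", lambda c, d: predict_nrc(c)),
            ("cncps", lambda c, d: predict_cncps(c)),
            ("jfs", lambda c, d: predict_jfs(c)),
        ]:
            preds, notes = predict_batch(records, name)
            assert notes == [None] * 100
            for p, (c, d) in zip(preds, records):
                assert p == fn(c, d)  # bit-for-bit

    def test_bad_record_flagged_not_raised(self):
        good = (CowState(bw=640, fcm=31.2, wol=5), DietComposition(ndf_pct=33.4))
        bad = (CowState(bw=640, wol=5), DietComposition(ndf_pct=33.4))  # no fcm
        preds, notes = predict_batch([good, bad], "kfsd")
        assert not math.isnan(preds[0]) and notes[0] is None
        assert math.isnan(preds[1]) and "fcm" in notes[1]


class TestStateValidation:
    def test_mbw_consistency_enforced(self):
        with pytest.raises(InvalidInputError):
            CowState(bw=640, mbw=100.0)

    def test_diet_ranges(self):
        with pytest.raises(InvalidInputError):
            DietComposition(ndf_pct=0.0)
        with pytest.raises(InvalidInputError):
            DietComposition(ndf_pct=30.0, adf_pct=35.0)
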