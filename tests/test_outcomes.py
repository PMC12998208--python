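"""MetS classification, CMRF standardization, CMRS construction and the
log2 back-transform."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pfasmix.outcomes import (
    back_transform_percent,
    classify_mets,
    compute_cmrs,
    percent_to_beta,
    standardize_cmrf,
)
from tests.conftest import make_record

# per-criterion (on, off) measurement overrides for a white male, no
# medications or diagnoses
_CRITERION_SETTINGS = {
    "wc_high": ({"wc": 103.0}, {"wc": 95.0}),
    "tg_high": ({"tg": 1.8}, {"tg": 1.0}),
    "hdl_low": ({"hdl": 0.9}, {"hdl": 1.5}),
    "bp_high": ({"sbp": 135.0}, {"sbp": 115.0}),
    "glyc_high": ({"hba1c": 6.0}, {"hba1c": 5.2}),
}


class TestMetSClassifier:
    def test_three_criteria_positive(self):
        rec = make_record(wc=103.0, tg=1.8, hdl=0.9)
        out = classify_mets(rec)
        assert out.loc[0, ["wc_high", "tg_high", "hdl_low"]].all()
        assert not out.loc[0, ["bp_high", "glyc_high"]].any()
        assert out.loc[0, "criteria_count"] == 3
        assert bool(out.loc[0, "mets"])

    def test_exhaustive_32_patterns_match_popcount_rule(self):
        """Over all 2^5 criterion vectors the classifier aggregate equals
        the brute-force ">= 3 of 5" rule (16 positive patterns)."""
        n_positive = 0
        for bits in itertools.product([0, 1], repeat=5):
            overrides = {}
            for on, crit in zip(bits, _CRITERION_SETTINGS):
                overrides.update(_CRITERION_SETTINGS[crit][0 if on else 1])
            out = classify_mets(make_record(**overrides))
            assert out.loc[0, "criteria_count"] == sum(bits)
            assert bool(out.loc[0, "mets"]) == (sum(bits) >= 3)
            n_positive += bool(out.loc[0, "mets"])
        assert n_positive == 16

    @pytest.mark.parametrize(
        "overrides,criterion,expected",
        [
            ({"wc": 102.0}, "wc_high", True),  # inclusive male threshold
            ({"wc": 101.9}, "wc_high", False),
            ({"sex": "female", "wc": 88.0}, "wc_high", True),
            ({"sex": "female", "wc": 87.9}, "wc_high", False),
            ({"asian_flag": True, "wc": 90.0}, "wc_high", True),
            ({"asian_flag": True, "wc": 89.9}, "wc_high", False),
            ({"sex": "female", "asian_flag": True, "wc": 81.0}, "wc_high", True),
            ({"sex": "female", "asian_flag": True, "wc": 79.0}, "wc_high", False),
            ({"tg": 1.7}, "tg_high", True),
            ({"tg": 1.699}, "tg_high", False),
            ({"hdl": 1.0}, "hdl_low", False),  # strict < for HDL
            ({"hdl": 0.999}, "hdl_low", True),
            ({"sex": "female", "hdl": 1.3}, "hdl_low", False),
            ({"sex": "female", "hdl": 1.299}, "hdl_low", True),
            ({"sbp": 130.0}, "bp_high", True),
            ({"dbp": 85.0}, "bp_high", True),
            ({"sbp": 129.9, "dbp": 84.9}, "bp_high", False),
            ({"hba1c": 5.7}, "glyc_high", True),
            ({"hba1c": 5.699}, "glyc_high", False),
        ],
    )
    def test_threshold_boundaries(self, overrides, criterion, expected):
        out = classify_mets(make_record(**overrides))
        assert bool(out.loc[0, criterion]) is expected

    @pytest.mark.parametrize(
        "flag,criteria",
        [
            ("med_lipid", ["tg_high", "hdl_low"]),
            ("med_bp", ["bp_high"]),
            ("dx_hypertension", ["bp_high"]),
            ("med_diabetes", ["glyc_high"]),
            ("dx_t2d", ["glyc_high"]),
        ],
    )
    def test_medication_and_diagnosis_flags_set_criteria(self, flag, criteria):
        out = classify_mets(make_record(**{flag: True}))
        for c in criteria:
            assert bool(out.loc[0, c])

    def test_missing_input_never_silently_classified(self):
        rec = make_record()
        rec.loc[0, "tg"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            classify_mets(rec)

    def test_glucose_variant_uses_glu_threshold(self):
        rec = make_record(glu=5.6, hba1c=5.0)
        assert bool(classify_mets(rec, glycemia="glu").loc[0, "glyc_high"])
        assert not bool(classify_mets(rec, glycemia="hba1c").loc[0, "glyc_high"])


class TestStandardization:
    def test_zero_residual_variance_errors(self):
        age = np.linspace(20, 79, 100)
        vals = 2.0 + 0.5 * age  # exact linear function of age
        sex = np.array(["male"] * 100)
        with pytest.raises(ValueError, match="zero residual variance"):
            standardize_cmrf(vals, age, sex)

    def test_weighted_moments_exact_by_construction(self):
        rng = np.random.default_rng(0)
        n = 500
        age = rng.uniform(20, 79, n)
        sex = rng.choice(["male", "female"], n)
        vals = 5 + 0.1 * age + rng.standard_normal(n)
        w = rng.uniform(0.5, 3.0, n)
        z = standardize_cmrf(vals, age, sex, w)
        assert abs(np.average(z, weights=w)) < 1e-10
        assert abs(np.average(z**2, weights=w) - 1.0) < 1e-10

    def test_reduces_to_plain_zscore_when_age_sex_unrelated(self):
        rng = np.random.default_rng(1)
        n = 200_000
        age = rng.uniform(20, 79, n)
        sex = rng.choice(["male", "female"], n)
        vals = rng.standard_normal(n)
        z = standardize_cmrf(vals, age, sex)
        plain = (vals - vals.mean()) / vals.std()
        assert np.max(np.abs(z - plain)) < 0.01

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError, match="n >= 50"):
            standardize_cmrf(np.ones(10), np.ones(10), ["male"] * 10)


class TestCMRS:
    @staticmethod
    def _z(**kw):
        cols = {f"z_{c}": [0.0] for c in ("wc", "hba1c", "tg", "hdl", "sbp", "dbp")}
        for k, v in kw.items():
            cols[f"z_{k}"] = [v]
        return pd.DataFrame(cols)

    def test_all_zero_z_gives_zero(self):
        assert compute_cmrs(self._z()).iloc[0] == 0.0

    def test_hand_computed_value(self):
        z = self._z(wc=1.0, hba1c=1.0, tg=1.0, hdl=1.0, sbp=1.0, dbp=1.0)
        # zMAP = 1, (1+1+1-1+1)/sqrt(5) = 3/sqrt(5)
        assert compute_cmrs(z).iloc[0] == pytest.approx(3 / np.sqrt(5), abs=1e-12)

    def test_hdl_is_protective_linear(self):
        base = compute_cmrs(self._z()).iloc[0]
        up = compute_cmrs(self._z(hdl=0.7)).iloc[0]
        assert up - base == pytest.approx(-0.7 / np.sqrt(5), abs=1e-12)

    def test_map_weighting_of_bp_components(self):
        # zMAP = zDBP + (zSBP - zDBP)/3 -> dbp weight 2/3, sbp weight 1/3
        dbp = compute_cmrs(self._z(dbp=1.0)).iloc[0]
        sbp = compute_cmrs(self._z(sbp=1.0)).iloc[0]
        assert dbp == pytest.approx((2 / 3) / np.sqrt(5), abs=1e-12)
        assert sbp == pytest.approx((1 / 3) / np.sqrt(5), abs=1e-12)

    def test_variance_under_independent_standard_normal_inputs(self):
        rng = np.random.default_rng(2)
        n = 200_000
        z = pd.DataFrame(
            {f"z_{c}": rng.standard_normal(n) for c in ("wc", "hba1c", "tg", "hdl", "sbp", "dbp")}
        )
        v = compute_cmrs(z).var()
        assert v == pytest.approx(41 / 45, rel=0.03)


class TestBackTransform:
    @pytest.mark.parametrize("beta,pct", [(0.0, 0.0), (1.0, 100.0), (-1.0, -50.0)])
    def test_known_values(self, beta, pct):
        assert back_transform_percent(beta) == pytest.approx(pct, abs=1e-12)

    def test_round_trip(self):
        for pct in (-35.0, 0.0, 1.16, 250.0):
            assert back_transform_percent(percent_to_beta(pct)) == pytest.approx(
                pct, abs=1e-12
            )
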