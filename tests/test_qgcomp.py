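"""Quantile g-computation: quantization, the psi = sum(beta) identity,
directional weights, and recovery of generator truth."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasmix.config import PFAS_NAMES, CohortConfig
from pfasmix.qgcomp import QGComp, fit_qgcomp, quantize, summarize_mixture
from pfasmix.synthetic import generate_cohort


class TestQuantize:
    def test_values_1_to_8_quartiles(self):
        q = quantize(pd.DataFrame({"a": np.arange(1.0, 9.0)}), q=4)
        assert q.scores["a"].tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_median_split(self):
        q = quantize(pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]}), q=2)
        assert q.scores["a"].tolist() == [0, 0, 1, 1]

    def test_tie_at_cutpoint_goes_to_lower_bin(self):
        x = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0, 4.0]})
        cuts = quantize(x, q=4).cutpoints["a"]
        # the interior quantiles themselves must land in the lower bin
        q2 = quantize(pd.DataFrame({"a": cuts}), q=4, cutpoints={"a": cuts})
        assert q2.scores["a"].tolist() == [0, 1, 2]

    def test_balanced_bins_on_continuous_data(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.standard_normal(4000)})
        counts = np.bincount(quantize(x, q=4).scores["a"])
        assert np.all(np.abs(counts - 1000) <= 1)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame({"a": rng.lognormal(size=97)})
        s1 = quantize(x, q=4).scores
        s2 = quantize(np.exp(x * 0.5) + 3.0, q=4).scores
        assert s1.equals(s2)

    def test_constant_analyte_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            quantize(pd.DataFrame({"a": np.ones(20)}))

    def test_q_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            quantize(pd.DataFrame({"a": [1.0, 2.0]}), q=4)


def _random_problem(seed, n=150, k=4):
    rng = np.random.default_rng(seed)
    expo = pd.DataFrame(
        rng.lognormal(size=(n, k)), columns=[f"e{j}" for j in range(k)]
    )
    cov = pd.DataFrame({"z": rng.standard_normal(n)})
    beta = rng.normal(scale=0.3, size=k)
    y = (
        quantize(expo).scores.to_numpy() @ beta
        + 0.5 * cov.z.to_numpy()
        + rng.standard_normal(n)
    )
    w = rng.uniform(0.5, 2.0, n)
    return expo, cov, y, w


class TestFit:
    def test_psi_is_exact_sum_of_coefficients(self):
        for seed in range(20):
            expo, cov, y, w = _random_problem(seed)
            f = QGComp().fit(expo, y, covariates=cov, sample_weight=w)
            assert f.psi_ == pytest.approx(f.exposure_coef_.sum(), abs=1e-12)

    def test_directional_weights_each_sum_to_one(self):
        """Normalization contract across 100 random datasets."""
        for seed in range(100):
            expo, cov, y, w = _random_problem(seed, n=120)
            f = QGComp().fit(expo, y, covariates=cov, sample_weight=w)
            if f.weights_positive_:
                assert sum(f.weights_positive_.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(v > 0 for v in f.weights_positive_.values())
            if f.weights_negative_:
                assert sum(f.weights_negative_.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(v > 0 for v in f.weights_negative_.values())
            assert len(f.weights_positive_) + len(f.weights_negative_) == len(
                f.exposure_coef_[f.exposure_coef_ != 0]
            )

    def test_single_exposure_mixture(self):
        expo, cov, y, w = _random_problem(3, k=1)
        f = QGComp().fit(expo, y, covariates=cov, sample_weight=w)
        assert f.psi_ == pytest.approx(f.exposure_coef_.iloc[0], abs=1e-12)
        wts = f.weights_positive_ or f.weights_negative_
        assert list(wts.values()) == pytest.approx([1.0])

    def test_independent_weighted_glm_oracle(self):
        expo, cov, y, w = _random_problem(5, n=400)
        f = QGComp().fit(expo, y, covariates=cov, sample_weight=w)
        X = sm.add_constant(
            pd.concat([quantize(expo).scores.astype(float), cov], axis=1)
        )
        o = sm.GLM(y, X, family=sm.families.Gaussian(), var_weights=w).fit()
        psi_oracle = o.params[list(expo.columns)].sum()
        assert abs(f.psi_ - psi_oracle) < 1e-8

    def test_scale_invariance_of_psi_and_weights(self):
        expo, cov, y, w = _random_problem(7)
        f1 = QGComp().fit(expo, y, covariates=cov, sample_weight=w)
        scaled = expo * np.array([3.0, 0.01, 7.0, 1000.0])
        f2 = QGComp().fit(scaled, y, covariates=cov, sample_weight=w)
        renamed = {k: v for k, v in f2.weights_positive_.items()}
        assert f2.psi_ == pytest.approx(f1.psi_, abs=1e-10)
        for k, v in f1.weights_positive_.items():
            assert renamed[k] == pytest.approx(v, abs=1e-10)

    def test_empty_exposure_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            QGComp().fit(pd.DataFrame(index=range(5)), np.zeros(5))

    def test_recovers_generator_truth_weights(self):
        """Truth shares (0.6, 0.4, 0, 0, 0) with all-positive coefficients:
        estimated positive weights within +-0.1 at n=5000."""
        cfg = CohortConfig(n_participants=5000, seed=21)
        truth = (0.6, 0.4, 0.0, 0.0, 0.0)
        cfg.true_weights["hba1c"] = truth
        cfg.true_psi["hba1c"] = 0.30
        c = generate_cohort(cfg)
        cov = pd.DataFrame(
            {
                "age10": (c.age - 50) / 10,
                "smoking_ever": (c.smoking == "ever").astype(float),
                "mvpa10": c.mvpa_min_per_day / 10,
                "female": (c.sex == "female").astype(float),
            }
        )
        f = QGComp().fit(
            c[list(PFAS_NAMES)], np.log2(c["hba1c"].to_numpy()), covariates=cov
        )
        w = f.weights_positive_
        for name, share in zip(PFAS_NAMES, truth):
            if share > 0:
                assert w.get(name, 0.0) == pytest.approx(share, abs=0.1)


class TestSummaries:
    def test_dataframe_wrapper_and_percent_summary(self):
        rng = np.random.default_rng(9)
        n = 300
        df = pd.DataFrame(rng.lognormal(size=(n, 3)), columns=["a", "b", "c"])
        df["z"] = rng.standard_normal(n)
        df["y"] = rng.standard_normal(n)
        f = fit_qgcomp(df, "y", ["a", "b", "c"], ["z"])
        row = summarize_mixture(f, "difference")
        assert row["estimate"] == pytest.approx(f.psi_)
        assert row["variant"] == "conditional-sum-of-coefficients"

    def test_percent_back_transform_of_small_psi(self):
        f = QGComp()
        f.psi_, f.psi_se_ = 0.0166, 0.0
        f.psi_ci_ = (0.0166, 0.0166)
        f.weights_positive_, f.weights_negative_ = {}, {}
        f.n_obs_, f.n_replicates_ = 0, 0
        row = summarize_mixture(f, "percent")
        assert row["estimate"] == pytest.approx(1.157, abs=0.01)

    def test_pr_summary_exponentiates(self):
        f = QGComp(family="poisson")
        f.psi_, f.psi_se_ = np.log(0.9), 0.0
        f.psi_ci_ = (np.log(0.9), np.log(0.9))
        f.weights_positive_, f.weights_negative_ = {}, {}
        f.n_obs_, f.n_replicates_ = 0, 0
        assert summarize_mixture(f, "pr")["estimate"] == pytest.approx(0.90)
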