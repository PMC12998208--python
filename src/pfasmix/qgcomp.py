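"""Quantile g-computation for chemical mixtures.

The estimator regresses the outcome on *quantized* exposures (each analyte
replaced by its quantile score 0..q-1) plus covariates, all survey-weighted.
The joint mixture effect per simultaneous one-quantile increase in every
exposure is

    psi = sum_j beta_j

over the quantized-exposure coefficients, and each analyte's contribution is
summarized by directional weights

    w_j+ = beta_j / sum_{beta_k > 0} beta_k   (for beta_j > 0)
    w_j- = beta_j / sum_{beta_k < 0} beta_k   (for beta_j < 0)

so weights in the same direction sum to 1.  This is the conditional
("sum of coefficients") variant of quantile g-computation; for the
poisson/log family exp(psi) is a conditional prevalence ratio.  The
marginalized bootstrap variant is intentionally out of scope and the variant
is recorded in output metadata.

Replicate-weight variance: quantile cutpoints are computed once on the full
analytic sample and held fixed across replicate refits, so replicate spread
reflects estimation, not binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survey import SurveyDesign, SurveyWeightedGLM, replicate_variance

__all__ = ["QuantizedExposures", "quantize", "QGComp", "fit_qgcomp", "summarize_mixture"]


@dataclass
class QuantizedExposures:
    """Per-analyte quantile scores plus the cutpoints that produced them."""

    scores: pd.DataFrame
    cutpoints: dict[str, np.ndarray]
    q: int = 4


def _quantize_column(x: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    # right-open bins: a value equal to a cutpoint goes to the LOWER bin
    return np.searchsorted(cuts, x, side="left").astype(np.int64)


def quantize(exposures, q: int = 4, cutpoints: dict | None = None) -> QuantizedExposures:
    """Assign each analyte its empirical quantile score in {0, ..., q-1}.

    Cutpoints are the q-1 interior empirical quantiles (linear
    interpolation).  Ties exactly at a cutpoint fall in the lower bin
    (right-open intervals).  Scores are rank-invariant: any strictly
    monotone transform of an analyte yields identical scores.
    """
    if not isinstance(exposures, pd.DataFrame):
        exposures = pd.DataFrame(exposures)
    n = len(exposures)
    if q < 2:
        raise ValueError("q must be >= 2")
    if cutpoints is None and q > n:
        raise ValueError(f"q={q} exceeds the number of observations ({n})")
    if exposures.isna().any().any():
        raise ValueError("exposures must be complete (no NaN) before quantization")
    probs = np.arange(1, q) / q
    scores = {}
    cuts_out = {}
    for col in exposures.columns:
        x = exposures[col].to_numpy(dtype=float)
        if cutpoints is not None:
            cuts = np.asarray(cutpoints[col], dtype=float)
        else:
            if np.min(x) == np.max(x):
                raise ValueError(f"analyte {col!r} is constant; quantiles undefined")
            cuts = np.quantile(x, probs)
        scores[col] = _quantize_column(x, cuts)
        cuts_out[col] = cuts
    return QuantizedExposures(pd.DataFrame(scores, index=exposures.index), cuts_out, q)


class QGComp(BaseEstimator):
    """Survey-weighted quantile g-computation estimator.

    Parameters
    ----------
    q : int
        Number of quantiles (4 = quartiles, the default).
    family : {"gaussian", "poisson"}
        Outcome family for the underlying weighted GLM; poisson/log on a
        binary outcome gives a prevalence-ratio mixture effect.
    alpha, variance_scale : passed to :class:`~pfasmix.survey.SurveyWeightedGLM`.

    Fitted attributes: ``psi_``, ``psi_se_``, ``psi_ci_``,
    ``exposure_coef_`` (pd.Series), ``weights_positive_``,
    ``weights_negative_`` (dicts, each summing to 1 when nonempty),
    ``cutpoints_``, ``glm_``, ``n_obs_``, ``n_replicates_``.
    """

    def __init__(
        self,
        q: int = 4,
        family: str = "gaussian",
        alpha: float = 0.05,
        variance_scale: float = 1.0,
    ):
        self.q = q
        self.family = family
        self.alpha = alpha
        self.variance_scale = variance_scale

    def fit(
        self,
        exposures,
        y,
        covariates=None,
        sample_weight=None,
        replicate_weights=None,
        design: SurveyDesign | None = None,
    ):
        if not isinstance(exposures, pd.DataFrame):
            exposures = pd.DataFrame(exposures)
        self.exposure_names_ = list(map(str, exposures.columns))
        if len(self.exposure_names_) == 0:
            raise ValueError("exposure set must be non-empty")
        quant = quantize(exposures, q=self.q)
        self.cutpoints_ = quant.cutpoints

        X = quant.scores.astype(float).copy()
        X.columns = [str(c) for c in X.columns]
        if covariates is not None:
            cov = (
                covariates
                if isinstance(covariates, pd.DataFrame)
                else pd.DataFrame(covariates)
            )
            for c in cov.columns:
                X[str(c)] = cov[c].to_numpy(dtype=float)
        X.insert(0, "(Intercept)", 1.0)

        glm = SurveyWeightedGLM(
            family=self.family, alpha=self.alpha, variance_scale=self.variance_scale
        )
        glm.fit(
            X,
            np.asarray(y, dtype=float),
            sample_weight=sample_weight,
            replicate_weights=replicate_weights,
            design=design,
        )
        self.glm_ = glm
        idx = [glm.term_names_.index(name) for name in self.exposure_names_]
        beta = glm.coef_[idx]
        self.exposure_coef_ = pd.Series(beta, index=self.exposure_names_)
        self.psi_ = float(np.sum(beta))

        if glm.replicate_coef_ is not None:
            rep_psi = glm.replicate_coef_[:, idx].sum(axis=1)
            self.replicate_psi_ = rep_psi
            var = replicate_variance(self.psi_, rep_psi, glm._variance_scale)
        else:
            self.replicate_psi_ = None
            # sandwich: var(sum beta_j) = 1' cov 1 over the exposure block
            var = float(np.sum(glm.cov_[np.ix_(idx, idx)]))
        self.psi_se_ = float(np.sqrt(max(var, 0.0)))
        zcrit = glm._crit()
        self.psi_ci_ = (
            self.psi_ - zcrit * self.psi_se_,
            self.psi_ + zcrit * self.psi_se_,
        )

        pos_sum = beta[beta > 0].sum()
        neg_sum = beta[beta < 0].sum()
        self.weights_positive_ = {
            n: float(b / pos_sum)
            for n, b in zip(self.exposure_names_, beta)
            if b > 0
        }
        self.weights_negative_ = {
            n: float(b / neg_sum)
            for n, b in zip(self.exposure_names_, beta)
            if b < 0
        }
        self.n_obs_ = glm.n_obs_
        self.n_replicates_ = glm.n_replicates_
        return self

    # -- reporting -------------------------------------------------------

    def summary(self, kind: str = "difference") -> dict:
        return summarize_mixture(self, kind)


def fit_qgcomp(
    data: pd.DataFrame,
    outcome: str,
    exposure_names: list[str],
    covariate_names: list[str] | None = None,
    family: str = "gaussian",
    design: SurveyDesign | None = None,
    q: int = 4,
    **kwargs,
) -> QGComp:
    """DataFrame-facing wrapper around :class:`QGComp`."""
    model = QGComp(q=q, family=family, **kwargs)
    cov = data[covariate_names] if covariate_names else None
    return model.fit(
        data[exposure_names],
        data[outcome].to_numpy(dtype=float),
        covariates=cov,
        design=design,
    )


def summarize_mixture(fit: QGComp, kind: str = "difference") -> dict:
    """One reporting row for a fitted mixture model.

    kind:
      * ``"difference"`` — psi as a mean difference (e.g. CMRS);
      * ``"pr"`` — exp(psi) prevalence ratio (binary outcome, log link);
      * ``"percent"`` — (2^psi - 1)*100 percent difference (log2 outcome).
    """
    lo, hi = fit.psi_ci_
    if kind == "difference":
        est, lo_t, hi_t = fit.psi_, lo, hi
    elif kind == "pr":
        est, lo_t, hi_t = float(np.exp(fit.psi_)), float(np.exp(lo)), float(np.exp(hi))
    elif kind == "percent":
        from .outcomes import back_transform_percent

        est = back_transform_percent(fit.psi_)
        lo_t = back_transform_percent(lo)
        hi_t = back_transform_percent(hi)
    else:
        raise ValueError(f"unknown summary kind {kind!r}")
    return {
        "psi": fit.psi_,
        "se": fit.psi_se_,
        "estimate": est,
        "ci_lower": lo_t,
        "ci_upper": hi_t,
        "estimate_type": kind,
        "weights_positive": dict(fit.weights_positive_),
        "weights_negative": dict(fit.weights_negative_),
        "n": fit.n_obs_,
        "n_replicates": fit.n_replicates_,
        "variant": "conditional-sum-of-coefficients",
    }
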