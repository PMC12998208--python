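"""Left-censored lognormal fitting and "fill-in" single imputation.

Concentrations below the analyte's limit of detection (LOD) are treated as
left-censored observations of a lognormal: detected values contribute the
lognormal density to the likelihood, non-detects contribute the CDF at
their LOD.  Maximum likelihood runs on the log scale via
``scipy.stats.CensoredData`` + ``norm.fit``.  Non-detects are then replaced
by a single draw from the fitted lognormal truncated to (0, LOD) — the
"fill-in" imputation — which yields unbiased downstream regression
coefficients when the imputation distribution is correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import CensoredData, norm
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CensoredLognormalParams",
    "fit_censored_lognormal",
    "fill_in_impute",
    "CensoredLogNormalImputer",
]

_MIN_DETECTED = 10


@dataclass(frozen=True)
class CensoredLognormalParams:
    log_mean: float
    log_sd: float
    converged: bool
    n_detected: int
    n_censored: int


def fit_censored_lognormal(values, nondetect_flags, lod) -> CensoredLognormalParams:
    """MLE of lognormal (log-mean, log-SD) under left-censoring at the LOD.

    Parameters
    ----------
    values : array-like
        Concentrations; entries flagged as non-detect may be NaN (masked).
    nondetect_flags : boolean array-like
        True where the measurement fell below the LOD.
    lod : scalar or array-like
        Limit of detection, either one value or per-record (per-cycle LODs).

    With zero non-detects this reduces to the closed-form MLE: mean and SD
    (ddof=0) of the log values.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(nondetect_flags, dtype=bool)
    lod = np.broadcast_to(np.asarray(lod, dtype=float), values.shape)
    det = values[~flags]
    if det.size < _MIN_DETECTED:
        raise ValueError(
            f"need at least {_MIN_DETECTED} detected values, got {det.size}"
        )
    if np.any(det <= 0) or np.any(~np.isfinite(det)):
        raise ValueError("detected concentrations must be positive and finite")
    if np.any(lod[flags] <= 0):
        raise ValueError("LOD must be > 0 wherever censoring occurs")
    logs = np.log(det)
    if np.ptp(logs) == 0 and not flags.any():
        raise ValueError(
            "degenerate data: zero variance among detected log concentrations"
        )
    n_cens = int(flags.sum())
    if n_cens == 0:
        mu, sd = float(np.mean(logs)), float(np.std(logs))
        if sd <= 0:
            raise ValueError("degenerate data: log-SD must be > 0")
        return CensoredLognormalParams(mu, sd, True, det.size, 0)
    data = CensoredData(uncensored=logs, left=np.log(lod[flags]))
    mu, sd = norm.fit(data)
    converged = bool(np.isfinite(mu) and np.isfinite(sd) and sd > 0)
    if not converged:
        raise RuntimeError(
            f"censored lognormal MLE failed to converge (mu={mu}, sd={sd}, "
            f"n_detected={det.size}, n_censored={n_cens})"
        )
    return CensoredLognormalParams(float(mu), float(sd), True, det.size, n_cens)


def fill_in_impute(values, nondetect_flags, lod, params, seed=None, rng=None):
    """Replace each non-detect by one draw from the fitted lognormal
    truncated to (0, LOD); detected values pass through bit-identical.

    Sampling is by inverse CDF: u ~ U(0, Phi((log LOD - mu)/sd)),
    x = exp(mu + sd * Phi^{-1}(u)).  Deterministic given the seed/rng.
    """
    if not isinstance(params, CensoredLognormalParams):
        raise TypeError("params must come from fit_censored_lognormal")
    values = np.asarray(values, dtype=float)
    flags = np.asarray(nondetect_flags, dtype=bool)
    out = values.copy()
    n_cens = int(flags.sum())
    if n_cens == 0:
        return out
    lod = np.broadcast_to(np.asarray(lod, dtype=float), values.shape)
    if rng is None:
        rng = np.random.default_rng(seed)
    zmax = (np.log(lod[flags]) - params.log_mean) / params.log_sd
    p_upper = ndtr(zmax)
    u = rng.uniform(0.0, 1.0, size=n_cens) * p_upper
    draws = np.exp(params.log_mean + params.log_sd * ndtri(u))
    # numerical guard: truncation contract is strict (0, LOD)
    draws = np.minimum(draws, lod[flags] * (1 - 1e-12))
    out[flags] = draws
    return out


class CensoredLogNormalImputer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: fit censored-lognormal parameters per
    analyte column, then fill in non-detects by truncated draws.

    Parameters
    ----------
    lod : dict mapping column -> LOD (scalar or per-record array)
    seed : int
        Global seed; each analyte gets an independent substream so that
        adding or dropping one analyte does not perturb the others.

    Fitted attribute: ``params_`` (dict column -> CensoredLognormalParams).
    """

    def __init__(self, lod: dict | None = None, seed: int = 0):
        self.lod = lod
        self.seed = seed

    def fit(self, X, y=None, nondetect=None):
        import pandas as pd

        X = pd.DataFrame(X)
        if nondetect is None:
            nondetect = X.isna()
        self.params_ = {}
        for col in X.columns:
            flags = np.asarray(nondetect[col], dtype=bool)
            self.params_[col] = fit_censored_lognormal(
                X[col].to_numpy(dtype=float), flags, self._lod_for(col)
            )
        self.columns_ = list(X.columns)
        return self

    def transform(self, X, nondetect=None):
        import pandas as pd

        X = pd.DataFrame(X)
        if nondetect is None:
            nondetect = X.isna()
        streams = np.random.SeedSequence(self.seed).spawn(len(self.columns_))
        out = X.copy()
        for col, ss in zip(self.columns_, streams):
            flags = np.asarray(nondetect[col], dtype=bool)
            out[col] = fill_in_impute(
                X[col].to_numpy(dtype=float),
                flags,
                self._lod_for(col),
                self.params_[col],
                rng=np.random.default_rng(ss),
            )
        return out

    def _lod_for(self, col):
        if self.lod is None:
            raise ValueError("lod mapping is required")
        return self.lod[col]
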