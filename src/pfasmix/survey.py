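"""Survey-weighted GLM estimation with bootstrap replicate-weight variance.

Two families are supported, matching what the analysis needs:

* ``gaussian`` (identity link) — survey-weighted linear regression for the
  continuous cardiometabolic outcomes;
* ``poisson`` (log link) — applied to a *binary* outcome this is the
  "modified Poisson" estimator of the prevalence ratio: the point estimate
  comes from the Poisson score equations while the variance comes from
  replicate-weight refits (or a robust sandwich when no replicate weights
  are supplied), never from the model-based Poisson variance.

Variance combination rule for B replicate weight vectors:

    Var(theta) = (scale / B) * sum_b (theta_b - theta_full)^2

with ``scale`` defaulting to 1, which is exact for the Rao–Wu–Yue rescaled
bootstrap produced by :mod:`pfasmix.synthetic`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri
from sklearn.base import BaseEstimator

__all__ = [
    "SurveyDesign",
    "SurveyWeightedGLM",
    "fit_weighted_glm",
    "estimate_pr",
    "replicate_variance",
]

_ETA_CLIP = 30.0


class SurveyDesign:
    """Main analysis weight plus optional replicate weight vectors.

    Parameters
    ----------
    weights : array-like of shape (n,)
        Main survey weights; strictly positive.
    replicate_weights : array-like of shape (n, B), optional
        Bootstrap replicate weight vectors, one column per replicate.
    scale : float
        Multiplier in the replicate variance rule ``(scale/B) * sum of
        squared deviations about the full-sample estimate``.
    """

    def __init__(self, weights, replicate_weights=None, scale: float = 1.0):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be one-dimensional")
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("all survey weights must be finite and > 0")
        self.weights = w
        if replicate_weights is not None:
            rw = np.asarray(replicate_weights, dtype=float)
            if rw.ndim != 2 or rw.shape[0] != w.shape[0]:
                raise ValueError(
                    "replicate_weights must have shape (n, B) aligned to weights"
                )
            if rw.shape[1] < 1:
                raise ValueError("need at least one replicate weight vector")
            self.replicate_weights = rw
        else:
            self.replicate_weights = None
        self.scale = float(scale)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_replicates(self) -> int:
        return 0 if self.replicate_weights is None else self.replicate_weights.shape[1]

    def subset(self, mask) -> "SurveyDesign":
        """Row-subset the design (e.g. for stratified or complete-case fits)."""
        mask = np.asarray(mask)
        rw = None if self.replicate_weights is None else self.replicate_weights[mask]
        return SurveyDesign(self.weights[mask], rw, self.scale)


def replicate_variance(full_estimate, replicate_estimates, scale: float = 1.0):
    """Replicate-weight variance about the full-sample estimate.

    ``(scale / B) * sum_b (theta_b - theta_full)^2``, applied along axis 0
    of ``replicate_estimates``.  Deterministic and invariant to replicate
    ordering.
    """
    reps = np.asarray(replicate_estimates, dtype=float)
    if reps.ndim == 1:
        reps = reps[:, None]
        squeeze = True
    else:
        squeeze = False
    B = reps.shape[0]
    if B < 1:
        raise ValueError("need at least one replicate estimate")
    dev = reps - np.asarray(full_estimate, dtype=float)
    var = (scale / B) * np.sum(dev * dev, axis=0)
    return float(var[0]) if squeeze else var


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_rank(X, names):
    """Raise naming the collinear columns if the model matrix is rank-deficient."""
    # QR with column pivoting via SVD-based rank; identify offenders by the
    # smallest right singular vectors.
    n, p = X.shape
    if n < p:
        raise ValueError(f"model matrix has more terms ({p}) than rows ({n})")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank < p:
        bad = set()
        for k in range(rank, p):
            idx = np.argsort(-np.abs(vt[k]))[:3]
            bad.update(names[i] for i in idx)
        raise np.linalg.LinAlgError(
            "rank-deficient model matrix; collinear terms involve: "
            + ", ".join(sorted(bad))
        )


def _wls_solve(X, Wy_weights, y):
    """Solve the weighted normal equations X'WX b = X'Wy.

    Falls back to least squares when a replicate weight vector zeroes out
    a category (rank checks on the MAIN fit happen separately).
    """
    XtW = X.T * Wy_weights
    A, b = XtW @ X, XtW @ y
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _irls_poisson(X, y, w, beta0=None, tol=1e-8, max_iter=100):
    """IRLS for a weighted Poisson/log-link GLM.  Returns (beta, n_iter)."""
    n, p = X.shape
    if beta0 is None:
        mu = np.clip((y + np.average(y, weights=w)) / 2.0, 1e-8, None)
        eta = np.log(mu)
        # one-step start: regress working response with mu weights
        z = eta + (y - mu) / mu
        beta = _wls_solve(X, w * mu, z)
    else:
        beta = np.array(beta0, dtype=float)
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta = _wls_solve(X, w * mu, z)
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * (np.log(y) - eta) - (y - mu), mu)
        dev = 2.0 * np.sum(w * dev_terms)
        if np.isfinite(dev) and abs(dev - dev_old) <= tol * (abs(dev) + 0.1):
            return beta, it
        dev_old = dev
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(last deviance {dev_old:.6g}); possible separation"
    )


class SurveyWeightedGLM(BaseEstimator):
    """Survey-weighted GLM with replicate-weight (or sandwich) variance.

    Parameters
    ----------
    family : {"gaussian", "poisson"}
        ``gaussian`` fits an identity-link linear model; ``poisson`` a
        log-link model.  A poisson fit on a 0/1 outcome is the modified
        Poisson prevalence-ratio estimator.
    alpha : float
        Two-sided confidence level complement (0.05 -> 95% Wald CI on the
        link scale, normal quantile, no df correction).
    use_t : bool
        If True, use a t quantile with B-1 (replicate) degrees of freedom
        instead of the normal quantile.
    variance_scale : float
        ``scale`` in the replicate variance rule.
    tol, max_iter : IRLS convergence controls (poisson family).

    Fitted attributes (trailing underscore): ``coef_``, ``se_``,
    ``ci_lower_``, ``ci_upper_``, ``replicate_coef_``, ``term_names_``,
    ``cov_type_``, ``n_obs_``, ``n_replicates_``, ``n_iter_``.
    """

    def __init__(
        self,
        family: str = "gaussian",
        alpha: float = 0.05,
        use_t: bool = False,
        variance_scale: float = 1.0,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.family = family
        self.alpha = alpha
        self.use_t = use_t
        self.variance_scale = variance_scale
        self.tol = tol
        self.max_iter = max_iter

    # -- estimation ------------------------------------------------------

    def _fit_one(self, X, y, w, beta0=None):
        if self.family == "gaussian":
            return _wls_solve(X, w, y), 1
        elif self.family == "poisson":
            return _irls_poisson(X, y, w, beta0, self.tol, self.max_iter)
        raise ValueError(f"unknown family {self.family!r}")

    def fit(self, X, y, sample_weight=None, replicate_weights=None, design=None):
        """Fit with main weights; refit once per replicate weight vector.

        ``design`` may be a :class:`SurveyDesign` (overriding the two weight
        arguments).  Complete cases are required: any NaN raises.
        """
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        if design is not None:
            sample_weight = design.weights
            replicate_weights = design.replicate_weights
            self._variance_scale = design.scale
        else:
            self._variance_scale = self.variance_scale
        n = Xm.shape[0]
        w = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if np.any(~np.isfinite(Xm)) or np.any(~np.isfinite(y)):
            raise ValueError("NaN/inf in model inputs: enforce complete cases upstream")
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
        _check_rank(Xm * np.sqrt(w)[:, None], names)

        beta, n_iter = self._fit_one(Xm, y, w)
        self.coef_ = beta
        self.term_names_ = names
        self.n_obs_ = n
        self.n_iter_ = n_iter
        self.family_ = self.family

        is_binary = np.all((y == 0) | (y == 1))
        eta = np.clip(Xm @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta) if self.family == "poisson" else eta
        if self.family == "poisson" and is_binary and np.any(mu > 1):
            warnings.warn(
                f"modified Poisson fit: {int(np.sum(mu > 1))} fitted "
                "probabilities exceed 1",
                RuntimeWarning,
                stacklevel=2,
            )

        if replicate_weights is not None:
            rw = np.asarray(replicate_weights, dtype=float)
            if rw.ndim != 2 or rw.shape[0] != n:
                raise ValueError("replicate_weights must be (n, B)")
            B = rw.shape[1]
            if self.family == "gaussian":
                # batched normal equations across replicates
                XtWX = np.einsum("np,nb,nq->bpq", Xm, rw, Xm, optimize=True)
                XtWy = np.einsum("np,nb,n->bp", Xm, rw, y, optimize=True)
                try:
                    rep = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    # a replicate zeroed out a category: per-replicate lstsq
                    rep = np.stack(
                        [
                            np.linalg.lstsq(XtWX[b], XtWy[b], rcond=None)[0]
                            for b in range(B)
                        ]
                    )
            else:
                rep = np.empty((B, len(beta)))
                for b in range(B):
                    rep[b], _ = self._fit_one(Xm, y, rw[:, b], beta0=beta)
            self.replicate_coef_ = rep
            self.n_replicates_ = B
            var = replicate_variance(beta, rep, self._variance_scale)
            self.cov_type_ = "replicate"
            self._df = B - 1
        else:
            # robust (sandwich) variance with the main weights
            self.replicate_coef_ = None
            self.n_replicates_ = 0
            glm_w = w * mu if self.family == "poisson" else w
            A = (Xm.T * glm_w) @ Xm
            score = w * (y - mu)
            meat = (Xm.T * score**2) @ Xm
            Ainv = np.linalg.inv(A)
            cov = Ainv @ meat @ Ainv
            var = np.diag(cov)
            self.cov_ = cov
            self.cov_type_ = "robust"
            self._df = n - Xm.shape[1]

        self.var_ = np.maximum(var, 0.0)
        self.se_ = np.sqrt(self.var_)
        z = self._crit()
        self.ci_lower_ = beta - z * self.se_
        self.ci_upper_ = beta + z * self.se_
        return self

    def _crit(self):
        if self.use_t:
            from scipy.stats import t

            return float(t.ppf(1 - self.alpha / 2, max(self._df, 1)))
        return float(ndtri(1 - self.alpha / 2))

    # -- post-fit --------------------------------------------------------

    def _term_index(self, term):
        try:
            return self.term_names_.index(term)
        except ValueError:
            raise KeyError(
                f"term {term!r} not in model (terms: {self.term_names_})"
            ) from None

    def coef_table(self) -> pd.DataFrame:
        """Tidy per-term estimates on the link scale."""
        return pd.DataFrame(
            {
                "term": self.term_names_,
                "estimate": self.coef_,
                "se": self.se_,
                "ci_lower": self.ci_lower_,
                "ci_upper": self.ci_upper_,
            }
        )

    def prevalence_ratio(self, term):
        """PR = exp(coef) with exponentiated Wald CI (poisson family only)."""
        if self.family != "poisson":
            raise ValueError("prevalence ratios require the poisson (log-link) family")
        j = self._term_index(term)
        return (
            float(np.exp(self.coef_[j])),
            float(np.exp(self.ci_lower_[j])),
            float(np.exp(self.ci_upper_[j])),
        )

    def predict(self, X):
        Xm, _ = _as_matrix(X)
        eta = Xm @ self.coef_
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)) if self.family == "poisson" else eta


def fit_weighted_glm(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    family: str = "gaussian",
    design: SurveyDesign | None = None,
    add_intercept: bool = True,
    **kwargs,
) -> SurveyWeightedGLM:
    """Formula-light wrapper: fit ``outcome ~ terms`` from a DataFrame.

    ``terms`` are taken as already-numeric columns of ``data`` (categorical
    expansion is the caller's job, see :func:`pfasmix.design_matrix.build_design`).
    """
    X = data[terms].copy()
    if add_intercept:
        X.insert(0, "(Intercept)", 1.0)
    model = SurveyWeightedGLM(family=family, **kwargs)
    return model.fit(X, data[outcome].to_numpy(dtype=float), design=design)


def estimate_pr(fit: SurveyWeightedGLM, term):
    """Prevalence ratio and 95% CI for one model term."""
    return fit.prevalence_ratio(term)
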