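"""scikit-learn style estimators.

Samples (rows of ``X``) are arrays; features (columns) are genes, i.e.
``X`` is the transpose of the genes-by-arrays matrices used in the file
formats.  All estimators follow the fit/transform contract, expose
``get_params``/``set_params`` and store fitted results in trailing-
underscore attributes, so they compose with sklearn pipelines.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CensoredExpressionMatrix
from .sampler import McmcConfig, rank_features, run_chain


# ----------------------------------------------------------------------
# Bayesian model
# ----------------------------------------------------------------------

class BayesianCensoredDE(BaseEstimator):
    """Hierarchical Bayesian normalization + differential expression.

    Fits the integrated model (array-effect normalization, truncated-
    normal imputation of below-detection-limit cells, mixture-prior
    effect selection) by Metropolis-within-Gibbs MCMC and ranks genes by
    the winner's-curse-corrected effect size |posterior mean delta|.

    Parameters
    ----------
    n_iterations, burn_in, thin, rw_step_logsigma2, n_chains
        Chain configuration; ``burn_in=None`` keeps the second half.
    random_state : int
        Seed; identical seeds give bit-identical fits.
    keep_draws : bool
        Retain per-iteration alpha/sigma2 draws on the summary.

    Attributes
    ----------
    summary_ : PosteriorSummary
    delta_mean_, prob_null_, prob_up_, prob_down_, alpha_mean_, sigma2_mean_ : per gene
    a0_mean_, a1_mean_ : per array
    feature_scores_ : |delta_mean_|, the ranking surface
    """

    def __init__(self, n_iterations: int = 20000, burn_in: int | None = None,
                 thin: int = 1, rw_step_logsigma2: float = 0.5,
                 n_chains: int = 1, random_state: int = 0,
                 keep_draws: bool = False):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.rw_step_logsigma2 = rw_step_logsigma2
        self.n_chains = n_chains
        self.random_state = random_state
        self.keep_draws = keep_draws

    def _build_data(self, X, y, detection_limit) -> CensoredExpressionMatrix:
        if isinstance(X, CensoredExpressionMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("condition labels y are required when X is a plain matrix")
        y = np.asarray(y)
        groups = np.unique(y)
        if len(groups) != 2:
            raise ValueError(f"expected exactly two condition labels, got {groups}")
        condition = np.where(y == groups[0], 1, 2)
        censored = np.isnan(X)
        if detection_limit is None:
            if censored.any():
                raise ValueError("detection_limit is required when X has censored (NaN) cells")
            detection_limit = np.full(X.shape[0], -np.inf)
        replicate = np.empty(X.shape[0], dtype=int)
        for c in (1, 2):
            idx = np.flatnonzero(condition == c)
            replicate[idx] = np.arange(len(idx))
        return CensoredExpressionMatrix(values=X.T, censored=censored.T,
                                        condition=condition, replicate=replicate,
                                        detection_limit=np.asarray(detection_limit, dtype=float))

    def fit(self, X, y=None, *, detection_limit=None):
        data = self._build_data(X, y, detection_limit)
        config = McmcConfig(n_iterations=self.n_iterations, burn_in=self.burn_in,
                            thin=self.thin, seed=self.random_state,
                            rw_step_logsigma2=self.rw_step_logsigma2,
                            n_chains=self.n_chains)
        summary = run_chain(data, config, keep_draws=self.keep_draws)
        self.summary_ = summary
        self.delta_mean_ = summary.delta_mean
        self.delta_ci_ = summary.delta_ci
        self.prob_null_ = summary.prob_null
        self.prob_up_ = summary.prob_up
        self.prob_down_ = summary.prob_down
        self.alpha_mean_ = summary.alpha_mean
        self.sigma2_mean_ = summary.sigma2_mean
        self.a0_mean_ = summary.a0_mean
        self.a1_mean_ = summary.a1_mean
        self.feature_scores_ = np.abs(summary.delta_mean)
        self.n_features_in_ = len(summary.delta_mean)
        return self

    def rank(self):
        """Genes ordered by |posterior mean delta| (descending)."""
        check_is_fitted(self, "summary_")
        return rank_features(self.summary_)


# ----------------------------------------------------------------------
# quantile normalization (Bolstad)
# ----------------------------------------------------------------------

class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every array to share one empirical intensity distribution.

    ``fit`` averages the sorted rows into a reference distribution;
    ``transform`` maps each row onto the reference by rank.  Ties within
    a row receive the mean of the reference values their span covers, so
    within-row ordering is preserved.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("number of genes differs from fit data")
        out = np.empty_like(X, dtype=float)
        ref = self.reference_
        cum = np.concatenate([[0.0], np.cumsum(ref)])
        n = X.shape[1]
        for i in range(X.shape[0]):
            order = np.argsort(X[i], kind="stable")
            sx = X[i][order]
            starts = np.flatnonzero(np.concatenate([[True], sx[1:] != sx[:-1]]))
            ends = np.concatenate([starts[1:], [n]])
            means = (cum[ends] - cum[starts]) / (ends - starts)
            out[i][order] = np.repeat(means, ends - starts)
        return out


# ----------------------------------------------------------------------
# VSN-style glog calibration
# ----------------------------------------------------------------------

class VSNNormalizer(TransformerMixin, BaseEstimator):
    """Variance-stabilizing normalization by affine + arcsinh calibration.

    Input is on the natural-log scale and is exponentiated to intensities
    internally.  Each array i gets an affine calibration (offset ``o_i``,
    scale ``s_i`` > 0) inside a generalized-log transform
    ``h_i(x) = arcsinh((x - o_i) / s_i)``; the parameters are fitted by
    iterative maximum likelihood under the assumption that transformed
    values share one variance across genes (per-gene means and the common
    variance are profiled out between array updates).  This is a plain ML
    fit of the glog model, not the published robust variant.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _transform_one(x, offset, log_scale):
        return np.arcsinh((x - offset) / np.exp(log_scale))

    def fit(self, X, y=None):
        from scipy.optimize import minimize

        X = check_array(X, ensure_min_samples=2)
        intens = np.exp(X)
        n_arrays, n_genes = intens.shape
        offsets = np.zeros(n_arrays)
        log_scales = np.log(np.maximum(intens.std(axis=1), 1e-6))

        h = np.stack([self._transform_one(intens[i], offsets[i], log_scales[i])
                      for i in range(n_arrays)])
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            mu = h.mean(axis=0)
            v = max(float(np.mean((h - mu) ** 2)), 1e-12)
            h_prev = h.copy()
            for i in range(n_arrays):
                x = intens[i]

                def neg_ll(params, x=x):
                    o, ls = params
                    s = np.exp(ls)
                    d = x - o
                    q2 = 1.0 / np.maximum(d * d + s * s, 1e-300)
                    q = np.sqrt(q2)
                    hi = np.arcsinh(d / s)
                    r = (hi - mu) / v
                    # Jacobian of the transform: h'(x) = ((x-o)^2 + s^2)^(-1/2)
                    f = float(np.sum(r * (hi - mu)) / 2.0 - 0.5 * np.sum(np.log(q2)))
                    g_o = float(np.sum(-r * q - d * q2))
                    g_ls = float(np.sum(-r * d * q + s * s * q2))
                    return f, np.array([g_o, g_ls])

                res = minimize(neg_ll, np.array([offsets[i], log_scales[i]]),
                               method="L-BFGS-B", jac=True,
                               options={"maxiter": 200})
                offsets[i], log_scales[i] = res.x
                h[i] = self._transform_one(x, offsets[i], log_scales[i])
            denom = max(float(np.abs(h_prev).mean()), 1e-12)
            change = float(np.abs(h - h_prev).mean()) / denom
            if change < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("VSN calibration did not converge; returning last iterate")
        self.offsets_ = offsets
        self.scales_ = np.exp(log_scales)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = n_genes
        return self

    def transform(self, X):
        check_is_fitted(self, "offsets_")
        X = check_array(X)
        if X.shape[0] != len(self.offsets_):
            raise ValueError("VSN parameters are per-array; array count differs from fit data")
        intens = np.exp(X)
        return np.stack([
            self._transform_one(intens[i], self.offsets_[i], np.log(self.scales_[i]))
            for i in range(X.shape[0])
        ])


# ----------------------------------------------------------------------
# moderated t-test (empirical Bayes variance shrinkage)
# ----------------------------------------------------------------------

def _trigamma_inverse(c: float) -> float:
    """Solve trigamma(y) = c for y > 0 by safeguarded Newton iteration."""
    if c <= 0:
        return np.inf
    # large y: trigamma(y) ~ 1/y; small y: ~ 1/y^2
    y = 0.5 + 1.0 / c
    for _ in range(100):
        f = special.polygamma(1, y) - c
        fp = special.polygamma(2, y)
        step = f / fp
        y_new = y - step
        if y_new <= 0:
            y_new = y / 2.0
        if abs(y_new - y) < 1e-12 * max(1.0, y):
            return float(y_new)
        y = y_new
    return float(y)


class ModeratedTTest(BaseEstimator):
    """Two-group moderated t-test with empirical Bayes variance shrinkage.

    Per-gene pooled residual variances s2_g on d_g degrees of freedom are
    shrunk toward a global prior variance s0^2 estimated, together with
    its prior degrees of freedom d0, by matching the first two moments of
    log s2_g to a scaled F distribution (digamma/trigamma moment
    equations).  The moderated statistic uses the shrunk variance
    s2_tilde = (d0*s0^2 + d_g*s2_g) / (d0 + d_g) and is referred to a t
    distribution on d0 + d_g degrees of freedom.

    ``prior_df`` forces d0 (0 recovers the classical pooled t-test);
    ``prior_df=None`` estimates it from the data.
    """

    def __init__(self, prior_df: float | None = None):
        self.prior_df = prior_df

    def fit(self, X, y):
        X = check_array(X, ensure_min_samples=4)
        y = np.asarray(y)
        groups = np.unique(y)
        if len(groups) != 2:
            raise ValueError(f"expected exactly two group labels, got {groups}")
        m1 = y == groups[0]
        m2 = y == groups[1]
        n1, n2 = int(m1.sum()), int(m2.sum())
        if min(n1, n2) < 2:
            raise ValueError("both groups need at least 2 arrays")
        g = X.shape[1]
        mean1 = X[m1].mean(axis=0)
        mean2 = X[m2].mean(axis=0)
        ss1 = ((X[m1] - mean1) ** 2).sum(axis=0)
        ss2 = ((X[m2] - mean2) ** 2).sum(axis=0)
        df = float(n1 + n2 - 2)
        s2 = (ss1 + ss2) / df

        if self.prior_df is not None:
            d0 = float(self.prior_df)
            s0_2 = float(np.median(s2)) if d0 > 0 else np.nan
        elif g < 3:
            warnings.warn("fewer than 3 genes: falling back to the ordinary t-test (d0 = 0)")
            d0, s0_2 = 0.0, np.nan
        else:
            d0, s0_2 = self._estimate_prior(s2, df)

        if d0 == 0.0:
            s2_post = s2.copy()
        elif np.isinf(d0):
            s2_post = np.full(g, s0_2)
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)

        lfc = mean2 - mean1
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        t = np.where((se == 0) & (lfc == 0), 0.0, t)
        df_total = d0 + df
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

        self.groups_ = groups
        self.lfc_ = lfc
        self.s2_ = s2
        self.s2_post_ = s2_post
        self.t_ = t
        self.p_ = p
        self.df_residual_ = df
        self.df_prior_ = d0
        self.s2_prior_ = s0_2
        self.df_total_ = df_total
        self.n_features_in_ = g
        return self

    @staticmethod
    def _estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
        ok = s2 > 0
        if ok.sum() < 3:
            return 0.0, np.nan
        e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
        e_bar = float(e.mean())
        n = e.size
        c = float(np.mean((e - e_bar) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)))
        if c <= 0:
            d0 = np.inf
            s0_2 = float(np.exp(e_bar))
        else:
            d0 = 2.0 * _trigamma_inverse(c)
            s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return d0, s0_2
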