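"""Probabilistic model for two-condition censored expression data.

The observation model is a two-condition ANOVA on natural-log
intensities

    y_g1r ~ N(alpha_g - delta_g/2 + beta_g1r, sigma2_g)
    y_g2r ~ N(alpha_g + delta_g/2 + beta_g2r, sigma2_g)

with a gene-dependent array effect beta_gcr = a0_cr * alpha_g + a1_cr,
made identifiable by forcing the replicate-mean of a0 and of a1 to zero
within each condition.  Gene variances share a lognormal hierarchy
sigma2_g ~ logNormal(mu, eta2).  The differential effect delta_g carries
a three-component mixture prior: a point mass at zero (not
differentially expressed) plus truncated normals on the positive
(up-regulated) and negative (down-regulated) half-lines; the point mass
is what shrinks effect sizes of chance winners back toward zero
(winner's-curse / Beavis-effect correction).

Notation convention used throughout the package: Normal(m, v) is
mean/VARIANCE, and Gamma(a, b) is shape/rate on precisions, so e.g.
N(0, 100) has standard deviation 10 and Gamma(0.001, 0.001) is the usual
vague precision prior.

This module only evaluates densities; all sampling lives in
:mod:`mirnorm.sampler`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CensoredExpressionMatrix

# mixture component codes for z_g
NULL, UP, DOWN = 0, 1, 2

_LOG_2PI = float(np.log(2.0 * np.pi))
_CONSTRAINT_TOL = 1e-8


@dataclass
class PriorConstants:
    """Fixed hyperprior constants.

    All vague by construction: a flat Dirichlet over the mixture weights,
    Gamma(0.001, 0.001) on every precision, variance 1000 on the global
    gene-effect mean and variance 100 on the remaining location
    parameters (mu, a0, a1, mu_plus, mu_minus).
    """

    dirichlet_alpha: tuple = (1.0, 1.0, 1.0)
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001
    var_gene_mean: float = 1000.0
    var_generic: float = 100.0

    def __post_init__(self) -> None:
        vals = (*self.dirichlet_alpha, self.gamma_shape, self.gamma_rate,
                self.var_gene_mean, self.var_generic)
        if any(v <= 0 for v in vals):
            raise ValueError("all prior constants must be strictly positive")


@dataclass
class HyperState:
    """One configuration of the hyperparameters.

    g_mean / s2 locate and scale the alpha prior; mu / eta2 parameterize
    the lognormal variance hierarchy; xi are the mixture weights
    (null, up, down); mu_plus / sigma2_plus and mu_minus / sigma2_minus
    parameterize the truncated-normal effect-size components.
    """

    g_mean: float
    s2: float
    mu: float
    eta2: float
    xi: np.ndarray
    mu_plus: float
    sigma2_plus: float
    mu_minus: float
    sigma2_minus: float

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.xi.shape != (3,) or np.any(self.xi < 0) or abs(self.xi.sum() - 1.0) > 1e-12:
            raise ValueError("xi must be a 3-simplex point (tolerance 1e-12)")
        if min(self.s2, self.eta2, self.sigma2_plus, self.sigma2_minus) <= 0:
            raise ValueError("variance hyperparameters must be positive")
        if not self.mu_plus > 0:
            raise ValueError("mu_plus must lie in the positive truncation support")
        if not self.mu_minus < 0:
            raise ValueError("mu_minus must lie in the negative truncation support")

    def copy(self) -> "HyperState":
        return HyperState(self.g_mean, self.s2, self.mu, self.eta2, self.xi.copy(),
                          self.mu_plus, self.sigma2_plus, self.mu_minus, self.sigma2_minus)


@dataclass
class ModelState:
    """One full set of latent parameters.

    ``y_complete`` holds the complete-data matrix: observed cells carry
    their measurements, censored cells the current imputed latent values
    (each bounded above by its array's detection limit).
    """

    alpha: np.ndarray
    delta: np.ndarray
    z: np.ndarray
    sigma2: np.ndarray
    a0: np.ndarray
    a1: np.ndarray
    y_complete: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int8)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.a0 = np.asarray(self.a0, dtype=float)
        self.a1 = np.asarray(self.a1, dtype=float)
        self.y_complete = np.asarray(self.y_complete, dtype=float)

    def copy(self) -> "ModelState":
        return ModelState(self.alpha.copy(), self.delta.copy(), self.z.copy(),
                          self.sigma2.copy(), self.a0.copy(), self.a1.copy(),
                          self.y_complete.copy())


# ----------------------------------------------------------------------
# mean structure
# ----------------------------------------------------------------------

def mean_structure(state: ModelState, gene: int, array: int, condition: int) -> float:
    """Model mean for one cell: alpha_g -/+ delta_g/2 + a0_a*alpha_g + a1_a."""
    if condition == 1:
        shift = -0.5 * state.delta[gene]
    elif condition == 2:
        shift = 0.5 * state.delta[gene]
    else:
        raise ValueError(f"unknown condition label {condition!r}; expected 1 or 2")
    a = state.alpha[gene]
    return float(a + shift + state.a0[array] * a + state.a1[array])


def mean_matrix(state: ModelState, data: CensoredExpressionMatrix) -> np.ndarray:
    """(G, A) matrix of model means for every cell."""
    return (np.outer(state.alpha, 1.0 + state.a0)
            + 0.5 * np.outer(state.delta, data.sign)
            + state.a1)


# ----------------------------------------------------------------------
# density pieces (plain numpy for speed; tests cross-check via scipy.stats)
# ----------------------------------------------------------------------

def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (np.asarray(x) - mean) ** 2 / var)


def _lognorm_logpdf(x, mu, eta2):
    lx = np.log(x)
    return _norm_logpdf(lx, mu, eta2) - lx


def _invgamma_logpdf(x, shape, rate):
    # density of 1/precision with precision ~ Gamma(shape, rate)
    from scipy.special import gammaln
    return shape * np.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(x) - rate / x


def _log_ndtr(x):
    from scipy.special import log_ndtr
    return log_ndtr(x)


def _trunc_norm_logpdf(x, mean, var, lower_half: bool):
    """logpdf of N(mean, var) truncated to (0, inf) (or (-inf, 0) if lower_half)."""
    sd = np.sqrt(var)
    if lower_half:
        log_z = _log_ndtr(-mean / sd)
        in_support = np.asarray(x) < 0
    else:
        log_z = _log_ndtr(mean / sd)
        in_support = np.asarray(x) > 0
    out = _norm_logpdf(x, mean, var) - log_z
    return np.where(in_support, out, -np.inf)


def delta_prior_logpdf(delta: np.ndarray, z: np.ndarray, hyper: HyperState) -> np.ndarray:
    """Per-gene log prior of (delta_g, z_g) under the mixture.

    For z = null the contribution is exactly log xi_1 (and -inf unless
    delta is exactly 0, the point mass being represented by the
    indicator itself).
    """
    with np.errstate(divide="ignore"):
        log_xi = np.log(hyper.xi)
    out = np.full(delta.shape, -np.inf)
    is_null = z == NULL
    out[is_null & (delta == 0.0)] = log_xi[0]
    up = z == UP
    if up.any():
        out[up] = log_xi[1] + _trunc_norm_logpdf(delta[up], hyper.mu_plus, hyper.sigma2_plus, False)
    down = z == DOWN
    if down.any():
        out[down] = log_xi[2] + _trunc_norm_logpdf(delta[down], hyper.mu_minus, hyper.sigma2_minus, True)
    return out


def _in_support(data, state, hyper) -> bool:
    if np.any(state.sigma2 <= 0):
        return False
    # mixture support: z = null <=> delta = 0; up => delta > 0; down => delta < 0
    if np.any((state.z == NULL) & (state.delta != 0.0)):
        return False
    if np.any((state.z == UP) & (state.delta <= 0.0)):
        return False
    if np.any((state.z == DOWN) & (state.delta >= 0.0)):
        return False
    # identifiability: replicate means of a0 and a1 vanish per condition
    for c in (1, 2):
        idx = data.arrays_in_condition(c)
        if abs(state.a0[idx].mean()) > _CONSTRAINT_TOL or abs(state.a1[idx].mean()) > _CONSTRAINT_TOL:
            return False
    # imputed values respect the detection limits
    if data.censored.any():
        lims = np.broadcast_to(data.detection_limit, data.values.shape)
        if np.any(state.y_complete[data.censored] > lims[data.censored] + 1e-12):
            return False
    return True


def log_joint(data: CensoredExpressionMatrix, state: ModelState,
              hyper: HyperState, constants: PriorConstants | None = None) -> float:
    """Complete-data log joint density of data and every parameter.

    Censored cells enter the Gaussian likelihood through their imputed
    values (data augmentation); the function returns -inf for any state
    outside the support (wrong mixture sign, violated identifiability
    constraint, imputed value above its detection limit, ...).

    The a0/a1 prior terms are the unconstrained N(0, var_generic)
    kernels evaluated on the sum-to-zero subspace; the constant subspace
    normalizer is omitted, which is irrelevant for MCMC and for
    term-wise comparisons.
    """
    constants = constants or PriorConstants()
    g, a = data.values.shape
    if state.alpha.shape != (g,) or state.a0.shape != (a,) or state.y_complete.shape != (g, a):
        raise ValueError("dimension mismatch between data and state")
    hyper.validate()
    if not _in_support(data, state, hyper):
        return -np.inf

    mu_mat = mean_matrix(state, data)
    loglik = float(np.sum(_norm_logpdf(state.y_complete, mu_mat, state.sigma2[:, None])))

    lp = loglik
    lp += float(np.sum(_norm_logpdf(state.alpha, hyper.g_mean, hyper.s2)))
    lp += float(np.sum(_lognorm_logpdf(state.sigma2, hyper.mu, hyper.eta2)))
    lp += float(np.sum(delta_prior_logpdf(state.delta, state.z, hyper)))
    lp += float(np.sum(_norm_logpdf(state.a0, 0.0, constants.var_generic)))
    lp += float(np.sum(_norm_logpdf(state.a1, 0.0, constants.var_generic)))

    # hyperpriors
    lp += float(_norm_logpdf(hyper.g_mean, 0.0, constants.var_gene_mean))
    lp += float(_invgamma_logpdf(hyper.s2, constants.gamma_shape, constants.gamma_rate))
    lp += float(_norm_logpdf(hyper.mu, 0.0, constants.var_generic))
    lp += float(_invgamma_logpdf(hyper.eta2, constants.gamma_shape, constants.gamma_rate))
    from scipy.special import gammaln
    a_dir = np.asarray(constants.dirichlet_alpha, dtype=float)
    with np.errstate(divide="ignore"):
        lp += float(gammaln(a_dir.sum()) - gammaln(a_dir).sum()
                    + np.sum((a_dir - 1.0) * np.log(np.maximum(hyper.xi, np.finfo(float).tiny))))
    lp += float(_trunc_norm_logpdf(hyper.mu_plus, 0.0, constants.var_generic, False))
    lp += float(_trunc_norm_logpdf(hyper.mu_minus, 0.0, constants.var_generic, True))
    lp += float(_invgamma_logpdf(hyper.sigma2_plus, constants.gamma_shape, constants.gamma_rate))
    lp += float(_invgamma_logpdf(hyper.sigma2_minus, constants.gamma_shape, constants.gamma_rate))
    return lp
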