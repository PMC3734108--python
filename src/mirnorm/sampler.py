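"""Metropolis-within-Gibbs engine for the censored hierarchical model.

One sweep updates, in order: imputed censored values (truncated-normal
data augmentation), gene effects alpha (conjugate Gaussian), the
(z, delta) mixture (marginalized component weights, then a truncated
Gaussian for non-null delta), gene variances (random-walk Metropolis on
log sigma2), array effects a0/a1 (joint Gaussian conditioned exactly on
the within-condition sum-to-zero constraints), and all hyperparameters.

Every conditional that admits a closed form is sampled exactly; only the
lognormal variance layer and the truncated-normal scale hyperparameters
need Metropolis steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp

from ._truncnorm import sample_lower_truncated, sample_upper_truncated
from .data import CensoredExpressionMatrix
from .model import (DOWN, NULL, UP, HyperState, ModelState, PriorConstants,
                    log_joint, mean_matrix)

_LOG_2PI = float(np.log(2.0 * np.pi))
_DELTA_FLOOR = np.nextafter(0.0, 1.0)
# numerical guard for prior draws of vague inverse-gamma scales (shape 0.001):
# the analytic prior has most of its mass outside double range
_SCALE_CLIP = (1e-12, 1e12)


@dataclass
class McmcConfig:
    """Chain length and tuning knobs.

    ``burn_in=None`` means half of ``n_iterations``.  ``rw_step_logsigma2``
    is the random-walk standard deviation for the log-variance Metropolis
    updates (0.5 gives 20-60% acceptance on realistic data).
    """

    n_iterations: int = 20000
    burn_in: int | None = None
    thin: int = 1
    seed: int = 0
    rw_step_logsigma2: float = 0.5
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.n_iterations // 2
        if self.n_iterations <= 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("n_iterations, thin and n_chains must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.rw_step_logsigma2 <= 0:
            raise ValueError("rw_step_logsigma2 must be positive")


@dataclass
class PosteriorSummary:
    """Per-gene, per-array and hyperparameter posterior summaries."""

    gene_ids: list
    array_ids: list
    delta_mean: np.ndarray
    delta_ci: np.ndarray          # (G, 2): 2.5% / 97.5% quantiles
    prob_null: np.ndarray
    prob_up: np.ndarray
    prob_down: np.ndarray
    alpha_mean: np.ndarray
    sigma2_mean: np.ndarray
    a0_mean: np.ndarray
    a1_mean: np.ndarray
    hyper_mean: dict
    diagnostics: dict
    draws: dict = field(repr=False, default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.delta_mean)

    def to_frame(self):
        import pandas as pd

        ranking = rank_features(self)
        rank = np.empty(self.n_genes, dtype=int)
        rank[ranking["gene"].to_numpy()] = np.arange(1, self.n_genes + 1)
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "delta_mean": self.delta_mean,
            "delta_lo": self.delta_ci[:, 0],
            "delta_hi": self.delta_ci[:, 1],
            "prob_null": self.prob_null,
            "prob_up": self.prob_up,
            "prob_down": self.prob_down,
            "alpha_mean": self.alpha_mean,
            "sigma2_mean": self.sigma2_mean,
            "rank": rank,
        })


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------

def initialize_state(data: CensoredExpressionMatrix) -> tuple[ModelState, HyperState]:
    """Deterministic overdispersed-but-sane starting point.

    Censored cells start at half their detection limit on the intensity
    scale (L - log 2); alpha and sigma2 at gene-wise moments of that
    completed matrix; array and differential effects at zero; hypers at
    fixed neutral values.
    """
    y0 = data.values.copy()
    if data.censored.any():
        lims = np.broadcast_to(data.detection_limit, y0.shape)
        y0[data.censored] = lims[data.censored] - np.log(2.0)
    g = data.n_genes
    state = ModelState(
        alpha=y0.mean(axis=1),
        delta=np.zeros(g),
        z=np.full(g, NULL, dtype=np.int8),
        sigma2=np.maximum(y0.var(axis=1, ddof=1), 1e-4),
        a0=np.zeros(data.n_arrays),
        a1=np.zeros(data.n_arrays),
        y_complete=y0,
    )
    hyper = HyperState(g_mean=0.0, s2=100.0, mu=0.0, eta2=1.0,
                       xi=np.array([1 / 3, 1 / 3, 1 / 3]),
                       mu_plus=1.0, sigma2_plus=1.0,
                       mu_minus=-1.0, sigma2_minus=1.0)
    return state, hyper


# ----------------------------------------------------------------------
# conditional updates
# ----------------------------------------------------------------------

def impute_censored(state: ModelState, hyper: HyperState,
                    data: CensoredExpressionMatrix, rng) -> None:
    """Resample censored cells from N(mean, sigma2_g) truncated above at L_cr."""
    if not data.censored.any():
        return
    gi, ai = np.nonzero(data.censored)
    mu = mean_matrix(state, data)[gi, ai]
    sd = np.sqrt(state.sigma2[gi])
    bad = ~np.isfinite(mu) | ~np.isfinite(sd)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-finite imputation parameters at gene {data.gene_ids[gi[k]]!r}, "
            f"array {data.array_ids[ai[k]]!r}"
        )
    state.y_complete[gi, ai] = sample_upper_truncated(rng, mu, sd, data.detection_limit[ai])


def update_gene_effects(state: ModelState, hyper: HyperState,
                        data: CensoredExpressionMatrix | None, rng) -> None:
    """Exact Gaussian conditional for alpha_g.

    alpha enters every cell of gene g with coefficient (1 + a0_a), so the
    likelihood precision is sum_a (1 + a0_a)^2 / sigma2_g, combined with
    the N(g_mean, s2) prior.
    """
    g = state.alpha.shape[0]
    if data is None:
        state.alpha = hyper.g_mean + np.sqrt(hyper.s2) * rng.standard_normal(g)
        return
    x = 1.0 + state.a0
    r = state.y_complete - 0.5 * np.outer(state.delta, data.sign) - state.a1
    prec = np.sum(x * x) / state.sigma2 + 1.0 / hyper.s2
    if not np.all(prec > 0):
        raise ValueError("zero total precision in gene-effect update")
    num = (r @ x) / state.sigma2 + hyper.g_mean / hyper.s2
    state.alpha = num / prec + rng.standard_normal(g) / np.sqrt(prec)


def delta_component_logweights(state: ModelState, hyper: HyperState,
                               data: CensoredExpressionMatrix):
    """Marginal (over delta) log weights of the three mixture components.

    For gene g with residuals e_ga = y_ga - alpha_g(1 + a0_a) - a1_a the
    likelihood as a function of delta is a Gaussian kernel with precision
    tau_g = A / (4 sigma2_g) centered at dhat_g = 2 sum_a s_a e_ga / A
    (s_a = -1/+1 for condition 1/2).  The null weight is xi_1 times the
    likelihood at delta = 0; the up/down weights integrate the kernel
    against the truncated-normal priors in closed form (normal-normal
    convolution times the ratio of Gaussian CDF normalizers).

    Returns ``(logw, aux)`` where ``logw`` is (G, 3) with the common
    likelihood-at-zero factor removed, and ``aux`` holds the conditional
    truncated-Gaussian parameters (m*, v*) for the up and down draws.
    """
    n = data.n_arrays
    e = state.y_complete - np.outer(state.alpha, 1.0 + state.a0) - state.a1
    s_sum = e @ data.sign
    tau = n / (4.0 * state.sigma2)
    dhat = 2.0 * s_sum / n

    with np.errstate(divide="ignore"):
        log_xi = np.log(hyper.xi)

    def _half(mu0, s20, lower_half):
        v_star = 1.0 / (tau + 1.0 / s20)
        m_star = v_star * (tau * dhat + mu0 / s20)
        marg_var = 1.0 / tau + s20
        log_marg = -0.5 * (_LOG_2PI + np.log(marg_var) + (dhat - mu0) ** 2 / marg_var)
        sgn = -1.0 if lower_half else 1.0
        lw = (0.5 * tau * dhat ** 2 + 0.5 * (_LOG_2PI - np.log(tau)) + log_marg
              + log_ndtr(sgn * m_star / np.sqrt(v_star))
              - log_ndtr(sgn * mu0 / np.sqrt(s20)))
        return lw, m_star, v_star

    lw_up, m_up, v_up = _half(hyper.mu_plus, hyper.sigma2_plus, False)
    lw_down, m_down, v_down = _half(hyper.mu_minus, hyper.sigma2_minus, True)
    logw = np.stack([np.full(dhat.shape, log_xi[0]),
                     log_xi[1] + lw_up,
                     log_xi[2] + lw_down], axis=1)
    aux = {"m_up": m_up, "v_up": v_up, "m_down": m_down, "v_down": v_down}
    return logw, aux


def update_delta_mixture(state: ModelState, hyper: HyperState,
                         data: CensoredExpressionMatrix | None, rng) -> None:
    """Sample z_g from the marginalized weights, then delta_g | z_g."""
    g = state.delta.shape[0]
    if data is None:
        logw = np.broadcast_to(np.log(np.maximum(hyper.xi, np.finfo(float).tiny)), (g, 3)).copy()
        aux = {"m_up": np.full(g, hyper.mu_plus), "v_up": np.full(g, hyper.sigma2_plus),
               "m_down": np.full(g, hyper.mu_minus), "v_down": np.full(g, hyper.sigma2_minus)}
    else:
        logw, aux = delta_component_logweights(state, hyper, data)
    # log-space normalization with max subtraction
    logw = logw - logsumexp(logw, axis=1, keepdims=True)
    p = np.exp(logw)
    cum = np.cumsum(p, axis=1)
    u = rng.random((g, 1)) * cum[:, -1:]
    z = (u[:, 0] > cum[:, 0]).astype(np.int8) + (u[:, 0] > cum[:, 1]).astype(np.int8)

    delta = np.zeros(g)
    up = z == UP
    if up.any():
        d = sample_lower_truncated(rng, aux["m_up"][up], np.sqrt(aux["v_up"][up]), 0.0)
        delta[up] = np.maximum(d, _DELTA_FLOOR)
    down = z == DOWN
    if down.any():
        d = sample_upper_truncated(rng, aux["m_down"][down], np.sqrt(aux["v_down"][down]), 0.0)
        delta[down] = np.minimum(d, -_DELTA_FLOOR)
    state.z = z
    state.delta = delta


def _mh_accept(rng, log_ratio: np.ndarray) -> np.ndarray:
    """Vector Metropolis-Hastings accept decision; ratio >= 1 always accepts."""
    return np.log(rng.random(np.shape(log_ratio))) < log_ratio


def update_variances(state: ModelState, hyper: HyperState,
                     data: CensoredExpressionMatrix | None, rng,
                     step: float = 0.5) -> float:
    """Random-walk Metropolis on log sigma2_g.

    In log coordinates the lognormal prior times the Jacobian is the
    plain Gaussian N(log sigma2; mu, eta2), so the target is that kernel
    plus the Gaussian likelihood.  Returns the acceptance fraction.
    """
    if data is None:
        n, ssr = 0.0, np.zeros_like(state.sigma2)
    else:
        resid = state.y_complete - mean_matrix(state, data)
        ssr = np.sum(resid * resid, axis=1)
        n = float(data.n_arrays)
    theta = np.log(state.sigma2)
    # clamp keeps exp(theta) inside double range on prior-only chains with
    # near-flat scale hyperpriors; inert for any data-attached run
    prop = np.clip(theta + step * rng.standard_normal(theta.shape), -700.0, 700.0)

    def logp(th):
        return -0.5 * n * th - ssr / (2.0 * np.exp(th)) - (th - hyper.mu) ** 2 / (2.0 * hyper.eta2)

    accept = _mh_accept(rng, logp(prop) - logp(theta))
    state.sigma2 = np.where(accept, np.exp(prop), state.sigma2)
    return float(np.mean(accept))


def update_array_effects(state: ModelState, hyper: HyperState,
                         data: CensoredExpressionMatrix, rng,
                         constants: PriorConstants, prior_only: bool = False) -> None:
    """Joint Gaussian draw of (a0, a1) per condition under sum-to-zero constraints.

    Unconstrained, each array's (a0_a, a1_a) has an independent 2x2
    Gaussian full conditional from the weighted regression of
    u_ga = y_ga - (alpha_g +/- delta_g/2) on (alpha_g, 1) with N(0, 100)
    priors.  Because the covariate matrix and weights are shared by all
    arrays, the 2x2 posterior covariance V is identical across arrays,
    and exact Gaussian conditioning on the two linear constraints
    (sum_r a0_cr = 0, sum_r a1_cr = 0) reduces to the within-condition
    centering projection applied to the unconstrained draws.
    """
    if prior_only:
        v_mat = np.eye(2) * constants.var_generic
        chol = np.linalg.cholesky(v_mat)
        u = None
    else:
        u = state.y_complete - state.alpha[:, None] - 0.5 * np.outer(state.delta, data.sign)
        w = 1.0 / state.sigma2
        swa2 = float(np.sum(w * state.alpha ** 2))
        swa = float(np.sum(w * state.alpha))
        sw = float(np.sum(w))
        p_mat = np.array([[swa2, swa], [swa, sw]]) + np.eye(2) / constants.var_generic
        v_mat = np.linalg.inv(p_mat)
        chol = np.linalg.cholesky(v_mat)

    for c in (1, 2):
        idx = data.arrays_in_condition(c)
        r = len(idx)
        if prior_only:
            m = np.zeros((r, 2))
        else:
            b = np.stack([(u[:, idx] * (state.alpha / state.sigma2)[:, None]).sum(axis=0),
                          (u[:, idx] / state.sigma2[:, None]).sum(axis=0)], axis=1)  # (r, 2)
            m = b @ v_mat.T
        theta = m + rng.standard_normal((r, 2)) @ chol.T
        theta -= theta.mean(axis=0, keepdims=True)  # exact conditioning (see docstring)
        state.a0[idx] = theta[:, 0]
        state.a1[idx] = theta[:, 1]


def _sample_vague_scale(rng, shape: float, rate: float) -> float:
    """Draw 1/precision with precision ~ Gamma(shape, rate), on the log scale.

    Uses X = Gamma(shape+1) * U^(1/shape) so that shapes as small as
    0.001 do not underflow; the result is clipped to a wide finite range.
    """
    log_tau = np.log(rng.gamma(shape + 1.0)) + np.log(rng.random()) / shape - np.log(rate)
    log_scale = np.clip(-log_tau, np.log(_SCALE_CLIP[0]), np.log(_SCALE_CLIP[1]))
    return float(np.exp(log_scale))


def update_hyperparameters(state: ModelState, hyper: HyperState,
                           constants: PriorConstants, rng,
                           rw_step: float = 0.5) -> dict:
    """Gibbs/Metropolis updates of every hyperparameter; returns MH bookkeeping."""
    g = state.alpha.shape[0]
    diag = {}

    # ---- gene-effect location/scale: normal / inverse-gamma conjugacy
    prec = g / hyper.s2 + 1.0 / constants.var_gene_mean
    mean = (state.alpha.sum() / hyper.s2) / prec
    hyper.g_mean = float(mean + rng.standard_normal() / np.sqrt(prec))
    sse = float(np.sum((state.alpha - hyper.g_mean) ** 2))
    hyper.s2 = 1.0 / rng.gamma(constants.gamma_shape + 0.5 * g,
                               1.0 / (constants.gamma_rate + 0.5 * sse))

    # ---- lognormal variance hierarchy
    lsig = np.log(state.sigma2)
    prec = g / hyper.eta2 + 1.0 / constants.var_generic
    mean = (lsig.sum() / hyper.eta2) / prec
    hyper.mu = float(mean + rng.standard_normal() / np.sqrt(prec))
    sse = float(np.sum((lsig - hyper.mu) ** 2))
    hyper.eta2 = 1.0 / rng.gamma(constants.gamma_shape + 0.5 * g,
                                 1.0 / (constants.gamma_rate + 0.5 * sse))

    # ---- mixture weights: Dirichlet conjugacy on the z counts
    counts = np.bincount(state.z, minlength=3).astype(float)
    hyper.xi = rng.dirichlet(np.asarray(constants.dirichlet_alpha) + counts)

    # ---- truncated-normal effect components
    for comp, lower_half in ((UP, False), (DOWN, True)):
        d = state.delta[state.z == comp]
        n = d.size
        sgn = -1.0 if lower_half else 1.0
        if lower_half:
            mu_cur, s2_cur = hyper.mu_minus, hyper.sigma2_minus
        else:
            mu_cur, s2_cur = hyper.mu_plus, hyper.sigma2_plus

        if n == 0:
            # component empty: refresh from its prior
            if lower_half:
                mu_new = float(sample_upper_truncated(
                    rng, 0.0, np.sqrt(constants.var_generic), 0.0))
                mu_new = min(mu_new, -_DELTA_FLOOR)
            else:
                mu_new = float(sample_lower_truncated(
                    rng, 0.0, np.sqrt(constants.var_generic), 0.0))
                mu_new = max(mu_new, _DELTA_FLOOR)
            s2_new = _sample_vague_scale(rng, constants.gamma_shape, constants.gamma_rate)
            acc_mu = acc_s2 = np.nan
        else:
            # location: independence MH with the untruncated conjugate proposal;
            # the acceptance ratio reduces to the truncation normalizers
            prec_q = n / s2_cur + 1.0 / constants.var_generic
            m_q = (d.sum() / s2_cur) / prec_q
            sd_q = 1.0 / np.sqrt(prec_q)
            if lower_half:
                prop = float(sample_upper_truncated(rng, m_q, sd_q, 0.0))
                prop = min(prop, -_DELTA_FLOOR)
            else:
                prop = float(sample_lower_truncated(rng, m_q, sd_q, 0.0))
                prop = max(prop, _DELTA_FLOOR)
            sd_comp = np.sqrt(s2_cur)
            log_ratio = n * (log_ndtr(sgn * mu_cur / sd_comp) - log_ndtr(sgn * prop / sd_comp))
            acc_mu = bool(_mh_accept(rng, np.array(log_ratio)))
            mu_new = prop if acc_mu else mu_cur

            # scale: random-walk MH on log sigma2 against the truncated likelihood
            theta = np.log(s2_cur)
            prop_t = theta + rw_step * rng.standard_normal()

            def logp(th):
                s2 = np.exp(th)
                return (-constants.gamma_shape * th - constants.gamma_rate / s2
                        - 0.5 * n * (np.log(s2)) - np.sum((d - mu_new) ** 2) / (2.0 * s2)
                        - n * log_ndtr(sgn * mu_new / np.sqrt(s2)))

            acc_s2 = bool(_mh_accept(rng, np.array(logp(prop_t) - logp(theta))))
            s2_new = float(np.exp(prop_t)) if acc_s2 else s2_cur

        if lower_half:
            hyper.mu_minus, hyper.sigma2_minus = mu_new, s2_new
            diag["accept_mu_minus"], diag["accept_sigma2_minus"] = acc_mu, acc_s2
        else:
            hyper.mu_plus, hyper.sigma2_plus = mu_new, s2_new
            diag["accept_mu_plus"], diag["accept_sigma2_plus"] = acc_mu, acc_s2
    return diag


# ----------------------------------------------------------------------
# chain driver
# ----------------------------------------------------------------------

def _run_single_chain(data: CensoredExpressionMatrix, config: McmcConfig, seed_seq,
                      constants: PriorConstants, prior_only: bool,
                      fixed_hyper: HyperState | None, keep_draws: bool):
    rng = np.random.default_rng(seed_seq)
    state, hyper = initialize_state(data)
    if fixed_hyper is not None:
        hyper = fixed_hyper.copy()

    n_kept = (config.n_iterations - config.burn_in + config.thin - 1) // config.thin
    g, a = data.n_genes, data.n_arrays
    delta_draws = np.empty((n_kept, g))
    z_counts = np.zeros((g, 3))
    alpha_sum = np.zeros(g)
    sigma2_sum = np.zeros(g)
    a0_sum = np.zeros(a)
    a1_sum = np.zeros(a)
    hyper_names = ["g_mean", "s2", "mu", "eta2", "xi1", "xi2", "xi3",
                   "mu_plus", "sigma2_plus", "mu_minus", "sigma2_minus"]
    hyper_draws = np.empty((n_kept, len(hyper_names)))
    extra = {}
    if keep_draws:
        extra["alpha"] = np.empty((n_kept, g))
        extra["sigma2"] = np.empty((n_kept, g))

    acc_sigma2 = 0.0
    acc_counts = {"mu_plus": [0, 0], "sigma2_plus": [0, 0],
                  "mu_minus": [0, 0], "sigma2_minus": [0, 0]}
    kept = 0
    data_arg = None if prior_only else data
    for it in range(config.n_iterations):
        if not prior_only:
            impute_censored(state, hyper, data, rng)
        update_gene_effects(state, hyper, data_arg, rng)
        update_delta_mixture(state, hyper, data_arg, rng)
        acc_sigma2 += update_variances(state, hyper, data_arg, rng,
                                       step=config.rw_step_logsigma2)
        update_array_effects(state, hyper, data, rng, constants, prior_only=prior_only)
        if fixed_hyper is None:
            hdiag = update_hyperparameters(state, hyper, constants, rng,
                                           rw_step=config.rw_step_logsigma2)
            for key, tracker in acc_counts.items():
                acc = hdiag.get(f"accept_{key}")
                if acc is not None and not (isinstance(acc, float) and np.isnan(acc)):
                    tracker[0] += int(acc)
                    tracker[1] += 1

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if not prior_only:
                lj = log_joint(data, state, hyper, constants)
                if not np.isfinite(lj):
                    raise RuntimeError(
                        f"non-finite log joint at iteration {it}: "
                        f"sigma2 range ({state.sigma2.min():.3g}, {state.sigma2.max():.3g}), "
                        f"xi={hyper.xi}, delta range ({state.delta.min():.3g}, {state.delta.max():.3g})"
                    )
            delta_draws[kept] = state.delta
            z_counts[np.arange(g), state.z] += 1.0
            alpha_sum += state.alpha
            sigma2_sum += state.sigma2
            a0_sum += state.a0
            a1_sum += state.a1
            hyper_draws[kept] = [hyper.g_mean, hyper.s2, hyper.mu, hyper.eta2,
                                 hyper.xi[0], hyper.xi[1], hyper.xi[2],
                                 hyper.mu_plus, hyper.sigma2_plus,
                                 hyper.mu_minus, hyper.sigma2_minus]
            if keep_draws:
                extra["alpha"][kept] = state.alpha
                extra["sigma2"][kept] = state.sigma2
            kept += 1

    diag = {
        "n_kept": kept,
        "accept_sigma2": acc_sigma2 / config.n_iterations,
        **{f"accept_{k}": (v[0] / v[1] if v[1] else float("nan"))
           for k, v in acc_counts.items()},
    }
    draws = {"delta": delta_draws, "hyper": hyper_draws, "hyper_names": hyper_names, **extra}
    sums = (alpha_sum, sigma2_sum, a0_sum, a1_sum, z_counts)
    return draws, sums, diag


def run_chain(data: CensoredExpressionMatrix, config: McmcConfig,
              constants: PriorConstants | None = None, *,
              prior_only: bool = False, fixed_hyper: HyperState | None = None,
              keep_draws: bool = False) -> PosteriorSummary:
    """Run the Gibbs sampler and summarize the retained draws.

    Identical ``config.seed`` produces a bit-identical summary.  With
    ``prior_only=True`` all likelihood contributions are dropped (the
    data object supplies only shapes and condition labels), so the chain
    targets the joint prior — used for prior-reproduction checks.
    ``fixed_hyper`` freezes the hyperparameters at the given values.
    """
    constants = constants or PriorConstants()
    data.validate()
    seed_seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, all_sums, all_diag = [], [], []
    for ss in seed_seqs:
        draws, sums, diag = _run_single_chain(data, config, ss, constants,
                                              prior_only, fixed_hyper, keep_draws)
        all_draws.append(draws)
        all_sums.append(sums)
        all_diag.append(diag)

    delta_draws = np.concatenate([d["delta"] for d in all_draws], axis=0)
    hyper_draws = np.concatenate([d["hyper"] for d in all_draws], axis=0)
    n_kept_total = delta_draws.shape[0]
    z_counts = sum(s[4] for s in all_sums)
    alpha_mean = sum(s[0] for s in all_sums) / n_kept_total
    sigma2_mean = sum(s[1] for s in all_sums) / n_kept_total
    a0_mean = sum(s[2] for s in all_sums) / n_kept_total
    a1_mean = sum(s[3] for s in all_sums) / n_kept_total

    probs = z_counts / z_counts.sum(axis=1, keepdims=True)
    hyper_names = all_draws[0]["hyper_names"]
    draws = {"delta": delta_draws, "hyper": hyper_draws, "hyper_names": hyper_names}
    if keep_draws:
        draws["alpha"] = np.concatenate([d["alpha"] for d in all_draws], axis=0)
        draws["sigma2"] = np.concatenate([d["sigma2"] for d in all_draws], axis=0)

    diagnostics = {
        "n_kept": n_kept_total,
        "n_chains": config.n_chains,
        "seed": config.seed,
        "accept_sigma2": float(np.mean([d["accept_sigma2"] for d in all_diag])),
        "per_chain": all_diag,
    }
    return PosteriorSummary(
        gene_ids=list(data.gene_ids),
        array_ids=list(data.array_ids),
        delta_mean=delta_draws.mean(axis=0),
        delta_ci=np.quantile(delta_draws, [0.025, 0.975], axis=0).T,
        prob_null=probs[:, NULL],
        prob_up=probs[:, UP],
        prob_down=probs[:, DOWN],
        alpha_mean=alpha_mean,
        sigma2_mean=sigma2_mean,
        a0_mean=a0_mean,
        a1_mean=a1_mean,
        hyper_mean=dict(zip(hyper_names, hyper_draws.mean(axis=0))),
        diagnostics=diagnostics,
        draws=draws,
    )


def rank_features(summary: PosteriorSummary):
    """Rank genes by |posterior mean delta| (winner's-curse-corrected effect).

    Ties broken by larger posterior probability of differential
    expression (prob_up + prob_down), then by gene index.
    """
    import pandas as pd

    g = summary.n_genes
    score = np.abs(summary.delta_mean)
    tie = summary.prob_up + summary.prob_down
    order = np.lexsort((np.arange(g), -tie, -score))
    return pd.DataFrame({
        "gene": order,
        "gene_id": [summary.gene_ids[i] for i in order],
        "score": score[order],
        "prob_de": tie[order],
        "rank": np.arange(1, g + 1),
    })
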