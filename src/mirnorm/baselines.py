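"""Comparison arms: half-DL imputation, normalization, moderated t ranking.

The pipeline for every non-Bayesian arm is fixed: substitute censored
cells with half the detection limit on the intensity scale, normalize
(or not), then run the moderated t-test and rank by p-value.  These are
thin functional wrappers over the estimators in
:mod:`mirnorm.estimators`, operating on genes-by-arrays matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CensoredExpressionMatrix, MissingDetectionLimitError
from .estimators import ModeratedTTest, QuantileNormalizer, VSNNormalizer


@dataclass
class NormalizedMatrix:
    """Complete genes-by-arrays matrix after imputation/normalization."""

    values: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)):
            raise ValueError("normalized matrix must be complete and finite")


@dataclass
class ModeratedTestResult:
    """Per-gene moderated t statistics plus the global prior (d0, s0^2)."""

    lfc: np.ndarray
    s: np.ndarray
    s_tilde: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_residual: float
    df_prior: float
    s2_prior: float

    @property
    def df_total(self) -> float:
        return self.df_prior + self.df_residual


def impute_half_dl(data: CensoredExpressionMatrix) -> NormalizedMatrix:
    """Replace censored cells with half the detection limit.

    The substitution is on the intensity scale (0.5 * DL), i.e.
    L_cr - log 2 on the natural-log scale; observed cells are unchanged.
    """
    values = data.values.copy()
    if data.censored.any():
        needs = data.censored.any(axis=0)
        if np.any(needs & ~np.isfinite(data.detection_limit)):
            raise MissingDetectionLimitError("censored cell on an array without a detection limit")
        lims = np.broadcast_to(data.detection_limit, values.shape)
        values[data.censored] = lims[data.censored] - np.log(2.0)
    return NormalizedMatrix(values=values, method="none",
                            provenance={"imputation": "0.5*DL (intensity scale)"})


def _as_values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, NormalizedMatrix) else np.asarray(matrix, dtype=float)


def quantile_normalize(matrix) -> NormalizedMatrix:
    """Bolstad quantile normalization of a complete genes-by-arrays matrix."""
    values = _as_values(matrix)
    est = QuantileNormalizer().fit(values.T)
    out = est.transform(values.T).T
    return NormalizedMatrix(values=out, method="quantile",
                            provenance={"reference": "rank-wise mean across arrays"})


def vsn_normalize(matrix, max_iter: int = 100, tol: float = 1e-6) -> NormalizedMatrix:
    """Affine + arcsinh variance-stabilizing calibration (see VSNNormalizer)."""
    values = _as_values(matrix)
    est = VSNNormalizer(max_iter=max_iter, tol=tol).fit(values.T)
    out = est.transform(values.T).T
    return NormalizedMatrix(values=out, method="vsn",
                            provenance={"offsets": est.offsets_.tolist(),
                                        "scales": est.scales_.tolist(),
                                        "converged": est.converged_,
                                        "n_iter": est.n_iter_})


def moderated_t_test(matrix, condition) -> ModeratedTestResult:
    """Two-group moderated t-test on a complete genes-by-arrays matrix."""
    values = _as_values(matrix)
    est = ModeratedTTest().fit(values.T, np.asarray(condition))
    return ModeratedTestResult(lfc=est.lfc_, s=np.sqrt(est.s2_),
                               s_tilde=np.sqrt(est.s2_post_), t=est.t_, p=est.p_,
                               df_residual=est.df_residual_, df_prior=est.df_prior_,
                               s2_prior=est.s2_prior_)


def rank_by_pvalue(result: ModeratedTestResult) -> pd.DataFrame:
    """Genes ordered by ascending p; ties broken by larger |t|, then index."""
    g = len(result.p)
    order = np.lexsort((np.arange(g), -np.abs(result.t), result.p))
    return pd.DataFrame({
        "gene": order,
        "p": result.p[order],
        "t": result.t[order],
        "rank": np.arange(1, g + 1),
    })


_NORMALIZERS = {
    "quantile": quantile_normalize,
    "vsn": vsn_normalize,
    "none": lambda m: m,
}


def normalize_and_test(data: CensoredExpressionMatrix, method: str) -> ModeratedTestResult:
    """Fixed pipeline: impute 0.5*DL -> normalize (or identity) -> moderated t."""
    if method not in _NORMALIZERS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {sorted(_NORMALIZERS)}")
    imputed = impute_half_dl(data)
    normalized = _NORMALIZERS[method](imputed)
    return moderated_t_test(normalized, data.condition)
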