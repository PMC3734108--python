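"""Synthetic censored two-condition miRNA datasets with ground truth.

The generator emulates a two-condition spotted-array experiment: gene
effects uniform on (0, 10), gene-dependent linear array effects, gene
variances from a lognormal with log-mean -1.8 and log-sd 1 (matching the
spread seen on real arrays), and a three-component effect-size
distribution — a fraction ``sp`` of genes truly differentially expressed,
split evenly between up- and down-regulation at +/- log(3) fold change
(sd 0.1 on the log scale).  Left-censoring is induced per array by
marking every value strictly below the array's empirical m-quantile as
below the detection limit, with the quantile recorded as that array's
detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CensoredExpressionMatrix
from .model import DOWN, NULL, UP

_LABELS = {NULL: "null", UP: "up", DOWN: "down"}


@dataclass
class SimulationConfig:
    """Generator settings; the defaults define the study conditions.

    ``a0_scale``/``a1_scale`` are variances by default (Normal(m, v)
    notation); set ``array_effect_parameterization="sd"`` to read them as
    standard deviations instead.
    """

    n_genes: int = 300
    n_reps_per_condition: int = 5
    sp: float = 0.0
    m: float = 0.0
    alpha_range: tuple = (0.0, 10.0)
    a0_scale: float = 0.5
    a1_scale: float = 0.05
    array_effect_parameterization: str = "variance"
    sigma_mu: float = -1.8
    sigma_eta: float = 1.0
    effect_loc: float = float(np.log(3.0))
    effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sp < 1.0:
            raise ValueError("sp must lie in [0, 1)")
        if not 0.0 <= self.m < 1.0:
            raise ValueError("m must lie in [0, 1)")
        if self.array_effect_parameterization not in ("variance", "sd"):
            raise ValueError("array_effect_parameterization must be 'variance' or 'sd'")
        if self.n_reps_per_condition < 2:
            raise ValueError("need at least 2 replicate arrays per condition")


@dataclass
class SimulationTruth:
    """Generator ground truth for evaluating rankings."""

    alpha: np.ndarray
    delta: np.ndarray
    sigma2: np.ndarray
    a0: np.ndarray
    a1: np.ndarray
    de_label: np.ndarray          # per gene: "null" / "up" / "down"
    uncensored: np.ndarray        # (G, A) complete matrix before censoring

    @property
    def is_de(self) -> np.ndarray:
        return self.de_label != "null"


def _de_split(n_genes: int, sp: float) -> tuple[int, int]:
    """Deterministic rounding of the sp split: floor for up, remainder down."""
    n_de = int(round(sp * n_genes))
    n_up = n_de // 2
    return n_up, n_de - n_up


def apply_censoring(matrix: np.ndarray, m: float, condition: np.ndarray,
                    replicate: np.ndarray | None = None,
                    gene_ids=None, array_ids=None) -> CensoredExpressionMatrix:
    """Censor each array at its empirical m-quantile.

    The detection limit D_m is the linear-interpolation (type-7) quantile
    of the array's values; entries strictly below D_m are masked and D_m
    is recorded as the array's detection limit.
    """
    if not 0.0 <= m < 1.0:
        raise ValueError("m must lie in [0, 1)")
    matrix = np.asarray(matrix, dtype=float)
    g, a = matrix.shape
    condition = np.asarray(condition, dtype=int)
    if replicate is None:
        replicate = np.empty(a, dtype=int)
        for c in (1, 2):
            idx = np.flatnonzero(condition == c)
            replicate[idx] = np.arange(len(idx))
    limits = np.quantile(matrix, m, axis=0)  # linear interpolation between order stats
    censored = matrix < limits  # strictly below
    values = matrix.copy()
    values[censored] = np.nan
    return CensoredExpressionMatrix(values=values, censored=censored,
                                    condition=condition, replicate=replicate,
                                    detection_limit=limits,
                                    gene_ids=gene_ids, array_ids=array_ids)


def simulate_dataset(config: SimulationConfig) -> tuple[CensoredExpressionMatrix, SimulationTruth]:
    """Generate one censored dataset plus its ground truth; seeded and reproducible."""
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    r = config.n_reps_per_condition
    a = 2 * r
    condition = np.repeat([1, 2], r)
    replicate = np.tile(np.arange(r), 2)

    alpha = rng.uniform(*config.alpha_range, size=g)
    if config.array_effect_parameterization == "variance":
        a0_sd, a1_sd = np.sqrt(config.a0_scale), np.sqrt(config.a1_scale)
    else:
        a0_sd, a1_sd = config.a0_scale, config.a1_scale
    a0 = rng.normal(0.0, a0_sd, size=a)
    a1 = rng.normal(0.0, a1_sd, size=a)
    # center within condition so the truth satisfies the model's
    # identifiability constraint and is comparable to constrained posteriors
    for c in (1, 2):
        idx = np.flatnonzero(condition == c)
        a0[idx] -= a0[idx].mean()
        a1[idx] -= a1[idx].mean()

    sigma2 = np.exp(rng.normal(config.sigma_mu, config.sigma_eta, size=g))

    n_up, n_down = _de_split(g, config.sp)
    z = np.full(g, NULL, dtype=np.int8)
    z[:n_up] = UP
    z[n_up:n_up + n_down] = DOWN
    delta = np.zeros(g)
    delta[:n_up] = rng.normal(config.effect_loc, config.effect_sd, size=n_up)
    delta[n_up:n_up + n_down] = rng.normal(-config.effect_loc, config.effect_sd, size=n_down)
    perm = rng.permutation(g)
    z, delta = z[perm], delta[perm]

    sign = np.where(condition == 2, 1.0, -1.0)
    mean = np.outer(alpha, 1.0 + a0) + 0.5 * np.outer(delta, sign) + a1
    y = mean + rng.normal(size=(g, a)) * np.sqrt(sigma2)[:, None]

    data = apply_censoring(y, config.m, condition, replicate)
    truth = SimulationTruth(alpha=alpha, delta=delta, sigma2=sigma2, a0=a0, a1=a1,
                            de_label=np.array([_LABELS[int(k)] for k in z]),
                            uncensored=y)
    return data, truth
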