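"""Ranking evaluation (AUC, AUPRC) and the sp x m benchmark grid.

Each grid cell (sp, m, replicate) simulates one dataset, runs every
requested method on the same data, and scores the resulting per-gene
ranking against the simulation's ground-truth differential-expression
labels.  The Bayesian arm scores genes by |posterior mean delta|; the
moderated-t arms by 1 - p (p-value ranking needs a score orientation for
AUC).  Cells are seeded independently from the base seed so any cell can
be recomputed in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .baselines import normalize_and_test
from .sampler import McmcConfig, run_chain
from .simulate import SimulationConfig, simulate_dataset

ALL_METHODS = ("bayesian", "quantile", "vsn", "none")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve.

    Step-wise integration (precision at each recall increment, no linear
    interpolation between PR points), i.e. average precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("PR AUC needs at least one positive label")
    return float(average_precision_score(labels, scores))


@dataclass
class BenchmarkResult:
    """Long-format records of per-(sp, m, replicate, method) scores."""

    records: pd.DataFrame

    def medians(self) -> pd.DataFrame:
        """Median AUC/AUPRC per (sp, m, method) across replicates."""
        return (self.records
                .groupby(["sp", "m", "method"], as_index=False)[["auc", "auprc", "combined"]]
                .median())

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _cell_seeds(base_seed: int, sp: float, m: float, replicate: int) -> tuple[int, int]:
    """Stable per-cell seeds so any cell is recomputable in isolation."""
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(int(round(sp * 10000)), int(round(m * 10000)), replicate))
    sim_seed, mcmc_seed = (int(s) for s in ss.generate_state(2))
    return sim_seed, mcmc_seed


def score_methods(data, truth, methods, mcmc_config: McmcConfig) -> dict:
    """Run every method on one dataset and return {method: (auc, auprc)}."""
    labels = truth.is_de
    out = {}
    for method in methods:
        if method == "bayesian":
            summary = run_chain(data, mcmc_config)
            scores = np.abs(summary.delta_mean)
        else:
            result = normalize_and_test(data, method)
            scores = 1.0 - result.p
        out[method] = (roc_auc(scores, labels), pr_auc(scores, labels))
    return out


def run_benchmark_grid(sp_grid, m_grid, n_replicates: int,
                       methods=ALL_METHODS,
                       mcmc_config: McmcConfig | None = None,
                       sim_config: SimulationConfig | None = None,
                       base_seed: int = 0) -> BenchmarkResult:
    """Simulate and score every (sp, m, replicate) cell of the grid.

    ``sim_config`` provides the non-(sp, m, seed) generator settings;
    ``mcmc_config`` the chain settings for the Bayesian arm (its seed is
    replaced per cell).  A failing method leaves NaN scores for that cell
    and the run continues.
    """
    if not len(sp_grid) or not len(m_grid):
        raise ValueError("sp and m grids must be non-empty")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {ALL_METHODS}")
    mcmc_config = mcmc_config or McmcConfig()
    sim_template = sim_config or SimulationConfig()

    rows = []
    for sp in sp_grid:
        for m in m_grid:
            for rep in range(n_replicates):
                sim_seed, mcmc_seed = _cell_seeds(base_seed, sp, m, rep)
                cfg = SimulationConfig(
                    n_genes=sim_template.n_genes,
                    n_reps_per_condition=sim_template.n_reps_per_condition,
                    sp=sp, m=m,
                    alpha_range=sim_template.alpha_range,
                    a0_scale=sim_template.a0_scale,
                    a1_scale=sim_template.a1_scale,
                    array_effect_parameterization=sim_template.array_effect_parameterization,
                    sigma_mu=sim_template.sigma_mu,
                    sigma_eta=sim_template.sigma_eta,
                    effect_loc=sim_template.effect_loc,
                    effect_sd=sim_template.effect_sd,
                    seed=sim_seed,
                )
                data, truth = simulate_dataset(cfg)
                chain_cfg = McmcConfig(n_iterations=mcmc_config.n_iterations,
                                       burn_in=mcmc_config.burn_in,
                                       thin=mcmc_config.thin,
                                       seed=mcmc_seed,
                                       rw_step_logsigma2=mcmc_config.rw_step_logsigma2,
                                       n_chains=mcmc_config.n_chains)
                for method in methods:
                    try:
                        scored = score_methods(data, truth, [method], chain_cfg)
                        auc, auprc = scored[method]
                    except Exception as exc:  # noqa: BLE001 - record and continue
                        warnings.warn(f"method {method!r} failed at sp={sp}, m={m}, "
                                      f"rep={rep}: {exc}")
                        auc = auprc = np.nan
                    rows.append({"sp": sp, "m": m, "replicate": rep, "method": method,
                                 "auc": auc, "auprc": auprc,
                                 "combined": (auc + auprc) / 2.0,
                                 "seed": sim_seed})
    return BenchmarkResult(records=pd.DataFrame(rows))


def plot_benchmark(result: BenchmarkResult, out_prefix) -> list:
    """Boxplot of AUCs pooled over cells plus AUC-vs-sp / AUC-vs-m lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    rec = result.records.dropna(subset=["auc"])
    methods = sorted(rec["method"].unique())

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([rec.loc[rec["method"] == m, "auc"] for m in methods], tick_labels=methods)
    ax.set_ylabel("AUC")
    ax.set_title("AUC across all (sp, m) cells")
    path = f"{out_prefix}_auc_boxplot.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    med = result.medians()
    for param in ("sp", "m"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for m in methods:
            sub = med[med["method"] == m].groupby(param, as_index=False)["auc"].median()
            ax.plot(sub[param], sub["auc"], marker="o", label=m)
        ax.set_xlabel(param)
        ax.set_ylabel("median AUC")
        ax.legend()
        path = f"{out_prefix}_auc_vs_{param}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
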