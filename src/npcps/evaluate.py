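"""Benchmarking harness: ROC/AUC grids, change-point recovery, symmetry.

Reproduces the validation surfaces of the change-point method at
simulation scale: per-scenario AUCs of all eight gene-ranking statistics
on labelled null/DGE mixtures, the change-point recovery table on all-DGE
matrices, the over/under direction-symmetry experiment, and the pairwise
rank-correlation structure of the methods.

Scoring orientation: every method is evaluated as an over-expression
ranker unless ``mode="under"``.  For the change-point statistic the
over-expression score is ``-D_n`` (over-expressed tails push the signed
deviation negative); comparators use their over/under formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import comparators
from .changepoint import TestConfig, scan_matrix, true_change_fraction
from .simulate import SimulationConfig, gen_matrix

__all__ = [
    "ALL_METHODS",
    "Scenario",
    "auc",
    "roc_points",
    "score_genes",
    "score_all_methods",
    "roc_grid",
    "recovery_table",
    "direction_symmetry_experiment",
    "rank_correlation_matrix",
    "plot_roc",
]

ALL_METHODS = ("NPCPS", "LRS", "COPA", "OS", "ORT", "PPST", "T", "MOST")


def auc(null_scores, dge_scores) -> float:
    """Probability that a random DGE score exceeds a random null score.

    Mann-Whitney formulation with ties counted 1/2, identical to the
    trapezoidal area under the empirical ROC curve.  Scores must be
    finite.
    """
    null = np.asarray(null_scores, dtype=float).ravel()
    dge = np.asarray(dge_scores, dtype=float).ravel()
    if null.size == 0 or dge.size == 0:
        raise ValueError("both score vectors must be non-empty")
    if np.any(np.isnan(null)) or np.any(np.isnan(dge)):
        raise ValueError("scores contain NaN; resolve undefined statistics first")
    ranks = rankdata(np.concatenate([null, dge]))
    u = ranks[null.size:].sum() - dge.size * (dge.size + 1) / 2.0
    return float(u / (null.size * dge.size))


def roc_points(null_scores, dge_scores):
    """Empirical ROC curve ``(fpr, tpr)`` of a score, via scikit-learn."""
    from sklearn.metrics import roc_curve

    null = np.asarray(null_scores, dtype=float).ravel()
    dge = np.asarray(dge_scores, dtype=float).ravel()
    labels = np.concatenate([np.zeros(null.size), np.ones(dge.size)])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([null, dge]))
    return fpr, tpr


def score_genes(X, Y, method: str, mode: str = "over",
                cfg: TestConfig | None = None) -> np.ndarray:
    """Per-gene scores of one method on a genes-by-samples matrix pair.

    Undefined comparator values (NaN) are mapped to ``-inf`` — ranked as
    least differentially expressed — with a warning.
    """
    method = method.upper()
    if method == "NPCPS":
        stat, _, _, _ = scan_matrix(X, Y, cfg or TestConfig(alpha=0.01))
        scores = -stat if mode == "over" else stat
    elif method in comparators.COMPARATORS:
        scores = np.atleast_1d(
            np.asarray(comparators.COMPARATORS[method](X, Y, mode=mode), float)
        )
    else:
        raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")
    nan = np.isnan(scores)
    if np.any(nan):
        warnings.warn(
            f"{method}: {int(nan.sum())} undefined score(s) ranked last",
            RuntimeWarning,
            stacklevel=2,
        )
        scores = np.where(nan, -np.inf, scores)
    return scores


def score_all_methods(X, Y, methods=ALL_METHODS, mode: str = "over",
                      cfg: TestConfig | None = None) -> pd.DataFrame:
    """Genes-by-methods score table (shared orientation)."""
    return pd.DataFrame(
        {m: score_genes(X, Y, m, mode=mode, cfg=cfg) for m in methods}
    )


@dataclass(frozen=True)
class Scenario:
    """One ROC design cell: group sizes, effect, DGE subset size, base law."""

    n1: int
    n2: int
    mu: float
    k: int
    base: str = "normal"
    shape: float = 5.0

    @property
    def label(self) -> str:
        tag = "" if self.base == "normal" else f" {self.base}({self.shape:g})"
        return f"n={self.n1 + self.n2} mu={self.mu:g} k={self.k}{tag}"


def _mixture(scn: Scenario, n_null: int, n_dge: int, seed: int):
    cfg = SimulationConfig(
        n1=scn.n1, n2=scn.n2, k=scn.k, mu=scn.mu, base=scn.base,
        shape=scn.shape, genes=n_null + n_dge, seed=seed,
        dge_fraction=n_dge / (n_null + n_dge),
    )
    return gen_matrix(cfg)


def roc_grid(scenarios, methods=ALL_METHODS, n_null: int = 1000,
             n_dge: int = 1000, seed: int = 0,
             cfg: TestConfig | None = None,
             keep_scores: bool = False) -> pd.DataFrame:
    """AUC of each method in each scenario on a labelled simulated mixture.

    One mixture of ``n_null`` null and ``n_dge`` DGE genes per scenario
    (per-scenario seeds derived from ``seed``).  Returns a tidy frame with
    one row per (scenario, method); with ``keep_scores`` the per-gene
    score table and truth labels are attached per row for ROC plotting.
    """
    cfg = cfg or TestConfig(alpha=0.01)
    rows = []
    children = np.random.SeedSequence(seed).generate_state(len(scenarios))
    for scn, child in zip(scenarios, children):
        mat = _mixture(scn, n_null, n_dge, int(child % np.iinfo(np.int32).max))
        scores = score_all_methods(mat.normal_values, mat.cancer_values,
                                   methods, cfg=cfg)
        for m in methods:
            s = scores[m].to_numpy()
            row = {
                "scenario": scn.label, "n1": scn.n1, "n2": scn.n2,
                "mu": scn.mu, "k": scn.k, "base": scn.base,
                "method": m, "auc": auc(s[~mat.is_dge], s[mat.is_dge]),
            }
            if keep_scores:
                row["scores"] = s
                row["is_dge"] = mat.is_dge
            rows.append(row)
    return pd.DataFrame(rows)


def recovery_table(n1: int = 25, n2: int = 25, mu: float = 2.0,
                   ks=(1, 3, 5, 7, 9, 12, 15, 20, 25), genes: int = 7000,
                   alpha: float = 0.01, seed: int = 0,
                   cfg: TestConfig | None = None) -> pd.DataFrame:
    """Change-point recovery and rejection rates on all-DGE matrices.

    For each ``k``: the actual change fraction ``(n-k)/n``, the mean
    estimated fraction tau_hat over all genes, the rejection rate, and the
    miss (non-rejection) rate at the configured critical value.
    """
    cfg = cfg or TestConfig(alpha=alpha)
    children = np.random.SeedSequence(seed).generate_state(len(ks))
    rows = []
    for k, child in zip(ks, children):
        sim = SimulationConfig(n1=n1, n2=n2, k=int(k), mu=mu, genes=genes,
                               seed=int(child % np.iinfo(np.int32).max))
        mat = gen_matrix(sim)
        _, _, tau, reject = scan_matrix(mat.normal_values, mat.cancer_values, cfg)
        rows.append({
            "k": int(k),
            "actual": true_change_fraction(n1, n2, int(k)),
            "mean_tau_hat": float(tau.mean()),
            "reject_rate": float(reject.mean()),
            "miss_rate": float(1.0 - reject.mean()),
        })
    return pd.DataFrame(rows)


def direction_symmetry_experiment(n1: int = 25, n2: int = 25, mu: float = 2.0,
                                  k: int = 8, methods=ALL_METHODS,
                                  n_null: int = 1000, n_dge: int = 1000,
                                  seed: int = 0,
                                  cfg: TestConfig | None = None) -> pd.DataFrame:
    """Over/under symmetry check: score with the matched and the mirrored
    formula on over-expressed (+mu) and under-expressed (-mu) mixtures.

    Returns one row per method with four AUCs:
    ``over_on_over`` (matched), ``under_on_under`` (matched, mirrored
    data), ``over_on_under`` and ``under_on_over`` (mismatched).  A
    direction-symmetric statistic keeps the two matched columns equal up
    to Monte Carlo error; direction-specific comparators collapse toward
    0.5 in the mismatched columns.
    """
    cfg = cfg or TestConfig(alpha=0.01)
    s_over, s_under = np.random.SeedSequence(seed).generate_state(2)
    scn_over = Scenario(n1, n2, abs(mu), k)
    scn_under = Scenario(n1, n2, -abs(mu), k)
    mat_over = _mixture(scn_over, n_null, n_dge, int(s_over % np.iinfo(np.int32).max))
    mat_under = _mixture(scn_under, n_null, n_dge, int(s_under % np.iinfo(np.int32).max))
    rows = []
    for m in methods:
        entry = {"method": m}
        for col, mat, mode in (
            ("over_on_over", mat_over, "over"),
            ("under_on_under", mat_under, "under"),
            ("over_on_under", mat_under, "over"),
            ("under_on_over", mat_over, "under"),
        ):
            s = score_genes(mat.normal_values, mat.cancer_values, m,
                            mode=mode, cfg=cfg)
            entry[col] = auc(s[~mat.is_dge], s[mat.is_dge])
        rows.append(entry)
    return pd.DataFrame(rows)


def rank_correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of the methods' rank vectors (Spearman without
    ties); input is a genes-by-methods score table, ranking descending."""
    ranks = scores.apply(lambda col: rankdata(-col.to_numpy()), axis=0)
    return ranks.corr(method="pearson")


def plot_roc(grid_row_scores, is_dge, label: str = "", ax=None):
    """Plot one empirical ROC curve from per-gene scores and truth labels."""
    import matplotlib.pyplot as plt

    fpr, tpr = roc_points(np.asarray(grid_row_scores)[~is_dge],
                          np.asarray(grid_row_scores)[is_dge])
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    return ax
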