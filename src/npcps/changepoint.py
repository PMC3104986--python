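"""Non-parametric change-point statistic (NPCPS) for cancer-outlier DGE.

A single gene's expression profile is treated as an ordered sequence with
the normal-group samples first and the cancer-group samples appended.
Differential expression confined to a subset of cancer samples manifests
as a change point: up to some position ``r`` the values follow the normal
reference distribution ``F1``, beyond it a shifted distribution ``F2``.

The statistic is a modified Kolmogorov distance.  ``F1`` is estimated by
the empirical CDF of the normal samples; its left-continuous generalized
inverse is evaluated on a fixed probability grid ``y_1 < ... < y_G``.  For
every candidate change point ``r`` the empirical CDF of the trailing
segment (length ``m = n - r``) is compared with the reference at each grid
quantile,

    D(r) = sqrt(m) * Delta(r),
    Delta(r) = signed deviation of maximal magnitude over the grid of
               ECDF_tail(F1^{-1}(y_j)) - y_j ,

and the reported statistic is ``D_n = D(r*)`` at the maximizing position
``r* = argmax_r |D(r)|``.  The sign of ``D_n`` carries the direction of
dysregulation: a tail whose CDF lies *above* the reference is shifted
toward small values (under-expression, positive ``D_n``), a tail whose CDF
lies below it is shifted toward large values (over-expression, negative
``D_n``).  The null hypothesis of no change point is rejected when
``|D_n|`` exceeds an asymptotic Kolmogorov critical value ``C(alpha)``.

The change-point fraction ``tau_hat = r*/n`` estimates how many cancer
samples carry the effect: ``n - r*`` of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KOLMOGOROV_CRITICAL",
    "GeneSequence",
    "ReferenceDistribution",
    "TestConfig",
    "NpcpsResult",
    "empirical_cdf",
    "empirical_quantile",
    "npcps_scan",
    "npcps_profile",
    "scan_matrix",
    "true_change_fraction",
    "detect_matrix",
]

#: Asymptotic Kolmogorov critical values C(alpha) for the supremum statistic.
KOLMOGOROV_CRITICAL = {0.05: 1.358, 0.01: 1.628}


def _as_finite_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def empirical_cdf(values, x):
    """Right-continuous empirical CDF of ``values`` evaluated at ``x``.

    Returns ``(1/m) * #{v_i <= x}``.  ``x`` may be a scalar or an array;
    ties in the sample are handled by the weak inequality.
    """
    arr = np.sort(_as_finite_1d(values, "values"))
    x = np.asarray(x, dtype=float)
    out = np.searchsorted(arr, x, side="right") / arr.size
    return float(out) if out.ndim == 0 else out


def empirical_quantile(values, y):
    """Left-continuous generalized inverse of the empirical CDF.

    Returns the smallest sample value ``v`` with ``ECDF(v) >= y``, for
    ``y`` strictly inside (0, 1).  ``y`` may be a scalar or an array.
    """
    arr = np.sort(_as_finite_1d(values, "values"))
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0.0) or np.any(y_arr >= 1.0):
        raise ValueError("probability level must lie strictly inside (0, 1)")
    idx = np.ceil(y_arr * arr.size).astype(np.intp) - 1
    out = arr[np.clip(idx, 0, arr.size - 1)]
    return float(out) if y_arr.ndim == 0 else out


@dataclass(frozen=True)
class GeneSequence:
    """One gene's expression values, normal samples first, cancer appended."""

    normal: np.ndarray
    cancer: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "normal", _as_finite_1d(self.normal, "normal"))
        object.__setattr__(self, "cancer", _as_finite_1d(self.cancer, "cancer"))
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both groups need at least 2 samples")

    @property
    def n1(self) -> int:
        return self.normal.size

    @property
    def n2(self) -> int:
        return self.cancer.size

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.normal, self.cancer])


@dataclass(frozen=True)
class ReferenceDistribution:
    """Normal-group reference: ECDF ``F1`` and its inverse on a fixed grid.

    The grid is ``y_j = j/(G+1)``, ``j = 1..G`` — equally spaced, avoiding
    0 and 1 where the inverse empirical CDF degenerates.
    """

    sorted_values: np.ndarray
    grid: np.ndarray
    quantiles: np.ndarray

    @classmethod
    def from_sample(cls, values, grid_size: int = 100) -> "ReferenceDistribution":
        arr = np.sort(_as_finite_1d(values, "values"))
        if grid_size < 1:
            raise ValueError("grid_size must be positive")
        grid = np.arange(1, grid_size + 1, dtype=float) / (grid_size + 1)
        quantiles = empirical_quantile(arr, grid)
        if arr[0] == arr[-1]:
            warnings.warn(
                "reference sample is constant; the reference distribution is a "
                "point mass",
                RuntimeWarning,
                stacklevel=2,
            )
        return cls(sorted_values=arr, grid=grid, quantiles=quantiles)

    @property
    def grid_size(self) -> int:
        return self.grid.size

    def cdf(self, x):
        return empirical_cdf(self.sorted_values, x)

    def quantile(self, y):
        return empirical_quantile(self.sorted_values, y)


@dataclass(frozen=True)
class TestConfig:
    """Test configuration: level, critical value, grid size, scan bounds.

    ``critical`` defaults to the asymptotic Kolmogorov value for ``alpha``
    (1.358 at 0.05, 1.628 at 0.01); any positive user value is accepted.
    ``min_tail`` is the shortest trailing segment scanned (default 2), so
    candidate change points run over ``r = 1 .. n - min_tail``.
    """

    __test__ = False  # keep pytest from collecting this dataclass

    alpha: float = 0.05
    critical: float | None = None
    grid_size: int = 100
    min_tail: int = 2

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.critical is None:
            try:
                object.__setattr__(
                    self, "critical", KOLMOGOROV_CRITICAL[round(self.alpha, 4)]
                )
            except KeyError:
                raise ValueError(
                    f"no tabulated critical value for alpha={self.alpha}; "
                    "pass critical= explicitly"
                ) from None
        if self.critical <= 0.0:
            raise ValueError("critical value must be positive")
        if self.grid_size < 10:
            raise ValueError("grid_size must be at least 10")
        if self.min_tail < 1:
            raise ValueError("min_tail must be at least 1")


@dataclass(frozen=True)
class NpcpsResult:
    """Outcome of the change-point scan for one gene.

    ``statistic`` is the signed ``D_n``; ``changepoint`` the 1-based index
    ``r*`` in the combined sequence; ``tau_hat = r*/n``.  ``direction`` is
    ``"over"`` (negative ``D_n``), ``"under"`` (positive) when the test
    rejects, else ``"none"``.
    """

    statistic: float
    changepoint: int
    tau_hat: float
    reject: bool
    direction: str
    n: int = field(default=0, compare=False)


def _scan_profile(normal: np.ndarray, cancer: np.ndarray, grid_size: int,
                  min_tail: int):
    """Signed D(r) over all candidate change points of one gene.

    Returns ``(r_values, D_values)`` where the tail at candidate ``r``
    consists of the combined-sequence positions ``r+1 .. n``.
    """
    ref = ReferenceDistribution.from_sample(normal, grid_size)
    z = np.concatenate([normal, cancer])
    n = z.size
    if n - min_tail < 1:
        raise ValueError("sequence too short for the requested scan range")
    # indicator[i, j] = 1{z_i <= F1^{-1}(y_j)}; suffix sums give tail counts
    indicator = z[:, None] <= ref.quantiles[None, :]
    suffix = np.cumsum(indicator[::-1], axis=0)[::-1]
    rs = np.arange(1, n - min_tail + 1)
    m = (n - rs).astype(float)
    delta = suffix[rs] / m[:, None] - ref.grid[None, :]
    # supremum over the grid; ties broken toward the smallest y_j
    j_star = np.argmax(np.abs(delta), axis=1)
    d_max = delta[np.arange(rs.size), j_star]
    return rs, np.sqrt(m) * d_max


def npcps_profile(seq: GeneSequence, cfg: TestConfig | None = None):
    """Per-candidate profile ``D(r)`` for diagnostics and plotting."""
    cfg = cfg or TestConfig()
    return _scan_profile(seq.normal, seq.cancer, cfg.grid_size, cfg.min_tail)


def npcps_scan(seq: GeneSequence, cfg: TestConfig | None = None) -> NpcpsResult:
    """Run the change-point scan on one gene.

    ``r*`` is the smallest candidate attaining the maximal ``|D(r)|``; the
    test rejects when ``|D_n| > C(alpha)``.
    """
    cfg = cfg or TestConfig()
    rs, D = _scan_profile(seq.normal, seq.cancer, cfg.grid_size, cfg.min_tail)
    i = int(np.argmax(np.abs(D)))  # ties -> smallest r
    d_n = float(D[i])
    r_star = int(rs[i])
    reject = abs(d_n) > cfg.critical
    if not reject or d_n == 0.0:
        direction = "none"
    else:
        direction = "over" if d_n < 0.0 else "under"
    return NpcpsResult(
        statistic=d_n,
        changepoint=r_star,
        tau_hat=r_star / seq.n,
        reject=reject,
        direction=direction,
        n=seq.n,
    )


def scan_matrix(normal: np.ndarray, cancer: np.ndarray,
                cfg: TestConfig | None = None):
    """Row-wise scan of a genes-by-samples matrix pair.

    ``normal`` and ``cancer`` are 2-D arrays with one row per gene.
    Returns ``(statistic, changepoint, tau_hat, reject)`` as 1-D arrays.
    Equivalent to :func:`npcps_scan` applied to each row.
    """
    cfg = cfg or TestConfig()
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    cancer = np.atleast_2d(np.asarray(cancer, dtype=float))
    if normal.shape[0] != cancer.shape[0]:
        raise ValueError("group matrices must have the same number of genes")
    g = normal.shape[0]
    stat = np.empty(g)
    cp = np.empty(g, dtype=int)
    for i in range(g):
        rs, D = _scan_profile(normal[i], cancer[i], cfg.grid_size, cfg.min_tail)
        j = int(np.argmax(np.abs(D)))
        stat[i] = D[j]
        cp[i] = rs[j]
    n = normal.shape[1] + cancer.shape[1]
    tau = cp / n
    reject = np.abs(stat) > cfg.critical
    return stat, cp, tau, reject


def true_change_fraction(n1: int, n2: int, k: int) -> float:
    """Actual change-point fraction when the last ``k`` of ``n2`` cancer
    samples carry the effect: ``(n1 + n2 - k) / (n1 + n2)``."""
    if not 0 < k <= n2:
        raise ValueError(f"k must satisfy 0 < k <= n2, got k={k}, n2={n2}")
    return (n1 + n2 - k) / (n1 + n2)


def detect_matrix(matrix, cfg: TestConfig | None = None):
    """Scan every gene of an expression matrix and rank the results.

    ``matrix`` is a :class:`npcps.io.GeneMatrix` (anything exposing
    ``genes``, ``normal_values`` and ``cancer_values`` works).  Genes with
    missing values are skipped with a warning; no imputation is attempted.

    Returns ``(table, summary)``: a DataFrame ranked by descending
    ``d_n`` (most positive — strongest under-expression — first, ties
    broken by gene id) with columns ``gene_id, rank, d_n, cp_index,
    cp_fraction, direction, reject``, and a dict of run counts.
    """
    cfg = cfg or TestConfig()
    genes = np.asarray(matrix.genes, dtype=object)
    X = np.asarray(matrix.normal_values, dtype=float)
    Y = np.asarray(matrix.cancer_values, dtype=float)
    complete = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    skipped = [str(gid) for gid in genes[~complete]]
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} gene(s) with missing values: "
            + ", ".join(skipped[:10]) + ("..." if len(skipped) > 10 else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    stat, cp, tau, reject = scan_matrix(X[complete], Y[complete], cfg)
    direction = np.where(reject, np.where(stat < 0, "over", "under"), "none")
    direction[(stat == 0.0)] = "none"
    table = pd.DataFrame(
        {
            "gene_id": genes[complete],
            "d_n": stat,
            "cp_index": cp,
            "cp_fraction": tau,
            "direction": direction,
            "reject": reject,
        }
    )
    table = table.sort_values(
        ["d_n", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    summary = {
        "n_genes": int(genes.size),
        "n_scanned": int(complete.sum()),
        "n_skipped": len(skipped),
        "skipped_genes": skipped,
        "n_positive": int((table["d_n"] > 0).sum()),
        "n_negative": int((table["d_n"] < 0).sum()),
        "n_rejected": int(table["reject"].sum()),
        "alpha": cfg.alpha,
        "critical": cfg.critical,
        "grid_size": cfg.grid_size,
    }
    return table, summary
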