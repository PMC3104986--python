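"""Comparator statistics for cancer-outlier differential expression.

Seven established gene-ranking statistics used to benchmark the
change-point scan: the pooled two-sample t-statistic (whole-group shift)
and six methods designed for effects confined to a subset of cancer
samples — COPA, OS, ORT, MOST (robust percentile/outlier-sum family),
PPST (percentile separability counts) and LRS (likelihood-ratio scan for
a mean-shifted top segment).

Conventions shared by every method here:

* input is a pair of 2-D arrays ``X`` (genes x normal samples) and ``Y``
  (genes x cancer samples); 1-D inputs are treated as a single gene;
* percentiles use linear interpolation between order statistics
  (``numpy.percentile`` default);
* MAD-type scale estimates carry the 1.4826 normal-consistency factor;
* ``mode="under"`` is computed as the over-expression statistic on
  negated data, which is algebraically the mirrored formula and makes the
  over/under reflection symmetry exact.

Larger statistic = stronger evidence of over-expression (in ``"over"``
mode) or under-expression (in ``"under"`` mode).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "t_statistic",
    "copa",
    "os_statistic",
    "ort",
    "most",
    "most_null_moments",
    "ppst",
    "lrs",
    "log_initialize",
    "COMPARATORS",
]

MAD_CONSISTENCY = 1.4826
_MOST_MOMENT_SEED = 20110531  # fixed: null moments must not vary between runs
_MOST_MOMENT_REPS = 100_000
_moment_cache: dict = {}


def _pair(X, Y):
    """Coerce to 2-D gene-by-sample arrays; report whether input was 1-D."""
    scalar = np.asarray(X).ndim == 1
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have one row per gene each")
    return X, Y, scalar


def _maybe_scalar(out, scalar):
    return float(out[0]) if scalar else out


def _oriented(X, Y, mode):
    if mode not in ("over", "under"):
        raise ValueError("mode must be 'over' or 'under'")
    return (X, Y) if mode == "over" else (-X, -Y)


def t_statistic(X, Y):
    """Pooled two-sample t-statistic, oriented cancer minus normal.

    Positive values indicate over-expression.  Genes with zero pooled
    variance get NaN (undefined statistic) and trigger a warning.
    """
    X, Y, scalar = _pair(X, Y)
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    diff = Y.mean(axis=1) - X.mean(axis=1)
    ss = X.var(axis=1, ddof=1) * (n1 - 1) + Y.var(axis=1, ddof=1) * (n2 - 1)
    pooled = ss / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    bad = se == 0.0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero pooled variance: "
            "t undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(bad, np.nan, diff / np.where(bad, 1.0, se))
    return _maybe_scalar(t, scalar)


def copa(X, Y, r_pct: float = 90.0, mode: str = "over"):
    """Cancer outlier profile analysis.

    Values are centred on the all-sample median and scaled by the
    all-sample MAD; the statistic is the ``r_pct``-th percentile of the
    standardized cancer values.  ``r_pct`` must exceed 50 (an upper-tail
    percentile).  Genes with zero MAD are undefined (NaN).
    """
    if not 50.0 < r_pct < 100.0:
        raise ValueError("r_pct must lie in (50, 100)")
    X, Y, scalar = _pair(X, Y)
    X, Y = _oriented(X, Y, mode)
    allv = np.hstack([X, Y])
    med = np.median(allv, axis=1, keepdims=True)
    mad = MAD_CONSISTENCY * np.median(np.abs(allv - med), axis=1)
    bad = mad == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (Y - med) / np.where(bad, 1.0, mad)[:, None]
    stat = np.percentile(z, r_pct, axis=1)
    stat = np.where(bad, np.nan, stat)
    return _maybe_scalar(stat, scalar)


def os_statistic(X, Y, mode: str = "over"):
    """Outlier sum.

    All values of a gene are standardized by the all-sample median and
    MAD; the statistic sums the standardized cancer values beyond the
    quartile fence Q3 + IQR of the gene's standardized values (over mode).
    No outliers gives 0.
    """
    X, Y, scalar = _pair(X, Y)
    X, Y = _oriented(X, Y, mode)
    allv = np.hstack([X, Y])
    med = np.median(allv, axis=1, keepdims=True)
    mad = MAD_CONSISTENCY * np.median(np.abs(allv - med), axis=1)
    bad = mad == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z_all = (allv - med) / np.where(bad, 1.0, mad)[:, None]
        z_can = (Y - med) / np.where(bad, 1.0, mad)[:, None]
    q1, q3 = np.percentile(z_all, [25, 75], axis=1)
    fence = (q3 + (q3 - q1))[:, None]
    stat = np.where(z_can > fence, z_can, 0.0).sum(axis=1)
    stat = np.where(bad, np.nan, stat)
    return _maybe_scalar(stat, scalar)


def _ort_scale(X, Y):
    """Robust scale from group-wise absolute deviations off group medians."""
    med_x = np.median(X, axis=1, keepdims=True)
    med_y = np.median(Y, axis=1, keepdims=True)
    dev = np.hstack([np.abs(X - med_x), np.abs(Y - med_y)])
    return med_x, MAD_CONSISTENCY * np.median(dev, axis=1)


def ort(X, Y, mode: str = "over"):
    """Outlier-robust t-statistic.

    Like the outlier sum but centred on the normal-group median, scaled by
    the pooled group-wise MAD, with the outlier fence computed from the
    normal-group quartiles: cancer values above Q3(x) + IQR(x) contribute
    ``(y - med_x) / mad``.
    """
    X, Y, scalar = _pair(X, Y)
    X, Y = _oriented(X, Y, mode)
    med_x, mad = _ort_scale(X, Y)
    bad = mad == 0.0
    q1, q3 = np.percentile(X, [25, 75], axis=1)
    fence = (q3 + (q3 - q1))[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (Y - med_x) / np.where(bad, 1.0, mad)[:, None]
    stat = np.where(Y > fence, u, 0.0).sum(axis=1)
    stat = np.where(bad, np.nan, stat)
    return _maybe_scalar(stat, scalar)


def most_null_moments(n2: int, n_reps: int = _MOST_MOMENT_REPS):
    """Null moments of cumulative top-k sums of n2 standard normal draws.

    Monte Carlo with a fixed seed: for each ``k = 1..n2`` the mean and
    standard deviation of ``sum of the k largest of n2 iid N(0,1)``.
    Results are cached per ``(n2, n_reps)``.
    """
    key = (int(n2), int(n_reps))
    if key not in _moment_cache:
        rng = np.random.default_rng(_MOST_MOMENT_SEED)
        draws = rng.standard_normal((n_reps, n2))
        draws.sort(axis=1)
        cums = np.cumsum(draws[:, ::-1], axis=1)
        _moment_cache[key] = (cums.mean(axis=0), cums.std(axis=0, ddof=1))
    return _moment_cache[key]


def most(X, Y, mode: str = "over"):
    """Maximum ordered-subset t-statistic.

    Cancer values are standardized ORT-style (normal-group median centre,
    pooled group-wise MAD scale) and sorted descending; the cumulative sum
    over the top ``k`` values is standardized by its Monte Carlo null
    moments, and the statistic is the maximum over ``k = 1..n2``.
    """
    X, Y, scalar = _pair(X, Y)
    X, Y = _oriented(X, Y, mode)
    med_x, mad = _ort_scale(X, Y)
    bad = mad == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (Y - med_x) / np.where(bad, 1.0, mad)[:, None]
    u = np.sort(u, axis=1)[:, ::-1]
    cums = np.cumsum(u, axis=1)
    mu_k, sigma_k = most_null_moments(Y.shape[1])
    stat = ((cums - mu_k) / sigma_k).max(axis=1)
    stat = np.where(bad, np.nan, stat)
    return _maybe_scalar(stat, scalar)


def ppst(X, Y, pct: float = 95.0, mode: str = "over"):
    """Percentile separability count.

    Over mode counts cancer samples above the ``pct``-th percentile of the
    normal group plus normal samples below the ``(100-pct)``-th percentile
    of the cancer group.  Integer-valued; larger = better separated.
    """
    if not 50.0 < pct < 100.0:
        raise ValueError("pct must lie in (50, 100)")
    X, Y, scalar = _pair(X, Y)
    X, Y = _oriented(X, Y, mode)
    hi_x = np.percentile(X, pct, axis=1)[:, None]
    lo_y = np.percentile(Y, 100.0 - pct, axis=1)[:, None]
    stat = (Y > hi_x).sum(axis=1) + (X < lo_y).sum(axis=1)
    return _maybe_scalar(stat.astype(float), scalar)


def lrs(X, Y, mode: str = "over", var_floor: float = 1e-8):
    """Likelihood-ratio scan for a mean-shifted top segment.

    Samples are arranged normals first, cancer values sorted ascending
    (over mode).  For every cut keeping the top ``t`` cancer values
    (``t = 1..n2-1``) the statistic of a normal mean-shift model with
    common variance is ``n * log(RSS0 / RSS1)``; the score is the maximum
    over cuts.  Within-segment variances are floored at ``var_floor``.
    """
    X, Y, scalar = _pair(X, Y)
    X, Y = _oriented(X, Y, mode)
    n1, n2 = X.shape[1], Y.shape[1]
    if n2 < 2:
        raise ValueError("LRS needs at least 2 cancer samples")
    n = n1 + n2
    ys = np.sort(Y, axis=1)
    total_s = X.sum(axis=1) + ys.sum(axis=1)
    total_ss = (X ** 2).sum(axis=1) + (ys ** 2).sum(axis=1)
    rss0 = total_ss - total_s ** 2 / n
    # suffix sums over the sorted cancer block: tail of size t = 1..n2-1
    tail_s = np.cumsum(ys[:, ::-1], axis=1)[:, :-1]
    tail_ss = np.cumsum(ys[:, ::-1] ** 2, axis=1)[:, :-1]
    t = np.arange(1, n2)
    head_s = total_s[:, None] - tail_s
    head_ss = total_ss[:, None] - tail_ss
    rss1 = (head_ss - head_s ** 2 / (n - t)) + (tail_ss - tail_s ** 2 / t)
    rss1 = np.maximum(rss1, n * var_floor)
    rss0 = np.maximum(rss0, n * var_floor)[:, None]
    stat = (n * np.log(rss0 / rss1)).max(axis=1)
    return _maybe_scalar(stat, scalar)


def log_initialize(values):
    """Natural-log transform applied to raw intensities before the
    comparator statistics (the change-point scan runs on raw values)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError("log initialization requires strictly positive values")
    return np.log(arr)


#: name -> scorer(X, Y, mode) for the seven comparator statistics, all
#: oriented so that larger means more differentially expressed in `mode`.
COMPARATORS = {
    "T": lambda X, Y, mode="over": t_statistic(X, Y) * (1 if mode == "over" else -1),
    "COPA": copa,
    "OS": os_statistic,
    "ORT": ort,
    "MOST": most,
    "PPST": ppst,
    "LRS": lrs,
}
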