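"""Synthetic expression matrices for the Monte Carlo and ROC experiments.

Each gene is an independent row: ``n1`` normal-group draws and ``n2``
cancer-group draws from a base law (standard normal, or standard
skew-normal with a shape parameter), with a constant effect ``mu`` added
to the *last* ``k`` cancer samples of genes that carry differential
expression.  Appending the affected samples last makes the true change
point of the combined sequence sit at position ``n - k``, i.e. fraction
``(n - k) / n`` — the quantity the change-point scan estimates.

Two layouts are produced:

* all-DGE (``dge_fraction=None``): every gene carries the effect; used
  for the false-positive-rate and change-point-recovery experiments;
* labelled mixture (``dge_fraction`` set): the first ``round(f * genes)``
  genes carry the effect, the rest are null; used for ROC studies.

Randomness comes from one root seed; each gene gets its own deterministic
substream, so changing the gene count never reshuffles earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulatedMatrix", "skew_normal_draw",
           "gen_gene", "gen_matrix"]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated dataset.

    ``base`` is ``"normal"`` or ``"skew-normal"``; ``shape`` only applies
    to the latter (default 5 — a markedly right-skewed law).  ``mu`` is
    the constant added to the last ``k`` cancer samples of DGE genes.
    """

    n1: int = 25
    n2: int = 25
    k: int = 9
    mu: float = 2.0
    base: str = "normal"
    shape: float = 5.0
    genes: int = 7000
    seed: int = 0
    dge_fraction: float | None = None

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both group sizes must be at least 2")
        if not 0 <= self.k <= self.n2:
            raise ValueError(f"k must satisfy 0 <= k <= n2, got {self.k}")
        if self.genes < 1:
            raise ValueError("genes must be at least 1")
        if self.base not in ("normal", "skew-normal"):
            raise ValueError("base must be 'normal' or 'skew-normal'")
        if not np.isfinite(self.mu) or not np.isfinite(self.shape):
            raise ValueError("mu and shape must be finite")
        if self.dge_fraction is not None and not 0.0 <= self.dge_fraction <= 1.0:
            raise ValueError("dge_fraction must lie in [0, 1]")


def skew_normal_draw(shape: float, rng: np.random.Generator, size=None):
    """Draws from the standard skew-normal law SN(0, 1, shape).

    Uses the half-normal mixing representation
    ``delta*|Z1| + sqrt(1-delta^2)*Z2`` with
    ``delta = shape / sqrt(1 + shape^2)``; ``shape=0`` reduces to N(0,1).
    """
    delta = shape / np.sqrt(1.0 + shape * shape)
    z1 = rng.standard_normal(size)
    z2 = rng.standard_normal(size)
    return delta * np.abs(z1) + np.sqrt(1.0 - delta * delta) * z2


def _draw_base(cfg: SimulationConfig, rng: np.random.Generator, size):
    if cfg.base == "normal":
        return rng.standard_normal(size)
    return skew_normal_draw(cfg.shape, rng, size)


def gen_gene(cfg: SimulationConfig, rng: np.random.Generator):
    """One gene: ``(normal_values, cancer_values)`` with ``mu`` added to
    the last ``k`` cancer samples."""
    x = _draw_base(cfg, rng, cfg.n1)
    y = _draw_base(cfg, rng, cfg.n2)
    if cfg.k > 0:
        y[cfg.n2 - cfg.k:] += cfg.mu
    return x, y


@dataclass(frozen=True)
class SimulatedMatrix:
    """Simulated genes-by-samples data with per-gene truth labels."""

    normal_values: np.ndarray  # (genes, n1)
    cancer_values: np.ndarray  # (genes, n2)
    is_dge: np.ndarray         # (genes,) bool
    config: SimulationConfig

    @property
    def genes(self):
        return np.array([f"gene{i + 1}" for i in range(self.is_dge.size)],
                        dtype=object)

    def to_frame(self) -> pd.DataFrame:
        """Genes-by-samples DataFrame (normal columns first)."""
        cols = [f"normal{j + 1}" for j in range(self.config.n1)] + [
            f"cancer{j + 1}" for j in range(self.config.n2)
        ]
        return pd.DataFrame(
            np.hstack([self.normal_values, self.cancer_values]),
            index=pd.Index(self.genes, name="gene_id"),
            columns=cols,
        )

    def labels_frame(self) -> pd.DataFrame:
        """Two-column sample-id / group table matching :meth:`to_frame`."""
        frame = self.to_frame()
        groups = ["normal"] * self.config.n1 + ["cancer"] * self.config.n2
        return pd.DataFrame({"sample_id": frame.columns, "group": groups})

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.genes, "is_dge": self.is_dge})


def gen_matrix(cfg: SimulationConfig) -> SimulatedMatrix:
    """Simulate a whole matrix under ``cfg``.

    With ``dge_fraction=None`` every gene carries the effect (all-DGE
    layout); otherwise the first ``round(dge_fraction * genes)`` genes do
    and the remainder are drawn with ``k=0``.
    """
    if cfg.dge_fraction is None:
        n_dge = cfg.genes
    else:
        n_dge = int(round(cfg.dge_fraction * cfg.genes))
    null_cfg = replace(cfg, k=0)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.genes)
    X = np.empty((cfg.genes, cfg.n1))
    Y = np.empty((cfg.genes, cfg.n2))
    is_dge = np.arange(cfg.genes) < n_dge
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        X[i], Y[i] = gen_gene(cfg if is_dge[i] else null_cfg, rng)
    return SimulatedMatrix(normal_values=X, cancer_values=Y,
                           is_dge=is_dge, config=cfg)
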