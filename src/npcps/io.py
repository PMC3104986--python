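"""Readers and writers for expression matrices, labels and results.

Matrices are plain TSV/CSV, genes in rows: a header row of sample ids and
a first column of gene ids.  Group membership comes either from a
two-column labels table (``sample_id``, ``group`` in {normal, cancer}) —
matched by sample id, not column position — or from explicit 1-based
column index ranges like ``"1-25"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneMatrix", "read_matrix", "read_labels", "parse_col_ranges",
           "write_table", "write_summary"]

log = logging.getLogger("npcps")

GROUPS = ("normal", "cancer")


@dataclass(frozen=True)
class GeneMatrix:
    """Expression values for g genes with a two-group sample partition."""

    genes: np.ndarray          # (g,) gene ids
    samples: np.ndarray        # (n,) sample ids, file order
    values: np.ndarray         # (g, n) float
    normal_idx: np.ndarray     # column positions of the normal group
    cancer_idx: np.ndarray     # column positions of the cancer group

    def __post_init__(self):
        n = self.samples.size
        both = np.concatenate([self.normal_idx, self.cancer_idx])
        if sorted(both.tolist()) != list(range(n)):
            raise ValueError("group indices must partition the sample columns")
        if self.normal_idx.size < 2 or self.cancer_idx.size < 2:
            raise ValueError("each group needs at least 2 samples")

    @property
    def n1(self) -> int:
        return self.normal_idx.size

    @property
    def n2(self) -> int:
        return self.cancer_idx.size

    @property
    def normal_values(self) -> np.ndarray:
        return self.values[:, self.normal_idx]

    @property
    def cancer_values(self) -> np.ndarray:
        return self.values[:, self.cancer_idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.genes, name="gene_id"),
                            columns=self.samples)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _dedupe(ids) -> list:
    seen: dict = {}
    out = []
    for gid in ids:
        gid = str(gid)
        if gid in seen:
            seen[gid] += 1
            new = f"{gid}.{seen[gid]}"
            log.warning("duplicate gene id %r renamed to %r", gid, new)
            out.append(new)
        else:
            seen[gid] = 0
            out.append(gid)
    return out


def read_labels(path) -> pd.Series:
    """Sample-id -> group mapping from a two-column TSV/CSV (header row
    ``sample_id``/``group`` optional)."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: labels file must have exactly two columns")
    first = df.iloc[0].str.lower().tolist()
    if first[1] in ("group", "label") or first[0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    groups = df.iloc[:, 1].str.strip().str.lower()
    bad = ~groups.isin(GROUPS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown group value(s) {sorted(groups[bad].unique())}; "
            f"expected one of {GROUPS}"
        )
    return pd.Series(groups.values, index=df.iloc[:, 0].str.strip().values)


def parse_col_ranges(spec: str, n_cols: int) -> np.ndarray:
    """Parse 1-based column ranges like ``"1-25"`` or ``"1-3,7,9-10"``."""
    idx: list[int] = []
    for part in str(spec).split(","):
        part = part.strip()
        if not part:
            continue
        lo, _, hi = part.partition("-")
        a = int(lo)
        b = int(hi) if hi else a
        if not (1 <= a <= b <= n_cols):
            raise ValueError(
                f"column range {part!r} outside 1..{n_cols}")
        idx.extend(range(a - 1, b))
    if len(set(idx)) != len(idx):
        raise ValueError(f"column ranges {spec!r} overlap")
    return np.asarray(idx, dtype=int)


def read_matrix(path, labels=None, normal_cols: str | None = None,
                cancer_cols: str | None = None) -> GeneMatrix:
    """Read a genes-by-samples matrix with its group assignment.

    ``labels`` is a labels-file path or a sample-id -> group Series;
    alternatively pass both ``normal_cols`` and ``cancer_cols`` as 1-based
    index ranges over the sample columns.  Non-numeric cells are hard
    errors naming the gene and sample; empty cells become NaN (such genes
    are later skipped by the scan).  Duplicate gene ids are suffixed.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                         comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.shape[1] < 4:
        raise ValueError(f"{path}: need at least 4 sample columns")
    genes = np.asarray(_dedupe(df.index), dtype=object)
    samples = np.asarray([str(c).strip() for c in df.columns], dtype=object)

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].str.strip() if df[col].dtype == object else df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw != "")
        if bad.any():
            gid = genes[int(np.flatnonzero(bad)[0])]
            cell = raw[bad].iloc[0]
            raise ValueError(
                f"{path}: non-numeric value {cell!r} at gene {gid!r}, "
                f"sample {col!r}"
            )
        values[:, j] = num.to_numpy(dtype=float)

    if labels is not None:
        mapping = labels if isinstance(labels, pd.Series) else read_labels(labels)
        missing = [s for s in samples if s not in mapping.index]
        if missing:
            raise ValueError(f"{path}: unlabelled sample column(s) {missing}")
        groups = np.asarray([mapping[s] for s in samples])
        normal_idx = np.flatnonzero(groups == "normal")
        cancer_idx = np.flatnonzero(groups == "cancer")
    elif normal_cols is not None and cancer_cols is not None:
        normal_idx = parse_col_ranges(normal_cols, samples.size)
        cancer_idx = parse_col_ranges(cancer_cols, samples.size)
    else:
        raise ValueError(
            "provide either labels or both normal_cols and cancer_cols")

    return GeneMatrix(genes=genes, samples=samples, values=values,
                      normal_idx=normal_idx, cancer_idx=cancer_idx)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep_for(path), index=index)


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
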