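"""Containers for weighted p-value families and subsets, with TSV input/output.

A :class:`WeightedPValues` holds the family ``p_1..p_L`` with weights
``w_1..w_L`` summing to one, optional per-test identifiers, and optional
genomic coordinates (chromosome, 1-based position).  A :class:`Subset` names
an index set R into a family; its weight ``wR`` is the sum of the member
weights and sets the subset-specific significance threshold ``alpha * wR``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["WeightedPValues", "Subset", "read_pvalues", "write_results"]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class Subset:
    """An index set R into a weighted p-value family.

    Parameters
    ----------
    indices : sequence of int
        Positions into the parent family; deduplicated and sorted.
    label : str, optional
        Human-readable name (e.g. a window identifier).
    interval : tuple, optional
        Genomic half-open interval ``(chrom, start, end)``, 0-based.
    """

    indices: tuple
    label: Optional[str] = None
    interval: Optional[tuple] = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size == 0:
            raise ValueError("subset must contain at least one index")
        if np.any(idx < 0):
            raise ValueError("subset indices must be non-negative")
        uniq = np.unique(idx)
        if uniq.size != idx.size:
            raise ValueError("subset indices must not contain duplicates")
        object.__setattr__(self, "indices", tuple(int(i) for i in uniq))

    def __len__(self) -> int:
        return len(self.indices)


class WeightedPValues:
    """A family of p-values with normalized non-negative weights.

    Parameters
    ----------
    p : array-like
        P-values, each in (0, 1].  Exact zeros are rejected: a zero p-value
        signals an upstream underflow that must be resolved before combining.
    w : array-like, optional
        Non-negative weights; default equal weights 1/L.  Weights not summing
        to one are renormalized with a warning.
    ids : sequence of str, optional
        Per-test labels.
    chrom, pos : array-like, optional
        Genomic coordinates; ``pos`` is 1-based.  Both or neither.
    """

    def __init__(self, p, w=None, ids=None, chrom=None, pos=None):
        p = np.asarray(p, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("p must be a non-empty 1-d vector")
        if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
            bad = np.flatnonzero(~((p > 0.0) & (p <= 1.0)))
            raise ValueError(
                f"p-values must lie in (0, 1]; offending indices {bad[:5].tolist()} "
                f"values {p[bad[:5]].tolist()}"
            )
        L = p.size
        if w is None:
            w = np.full(L, 1.0 / L)
        else:
            w = np.asarray(w, dtype=float)
            if w.shape != p.shape:
                raise ValueError("w must match p in length")
            if np.any(~np.isfinite(w)) or np.any(w < 0.0):
                raise ValueError("weights must be finite and non-negative")
            total = w.sum()
            if total <= 0.0:
                raise ValueError("at least one weight must be positive")
            if abs(total - 1.0) > _WEIGHT_TOL:
                warnings.warn(
                    f"weights sum to {total:g}; renormalizing to 1", UserWarning
                )
                w = w / total
        self.p = p
        self.w = w
        self.ids = list(ids) if ids is not None else None
        if self.ids is not None and len(self.ids) != L:
            raise ValueError("ids must match p in length")
        if (chrom is None) != (pos is None):
            raise ValueError("chrom and pos must be supplied together")
        if chrom is not None:
            chrom = np.asarray(chrom, dtype=object)
            pos = np.asarray(pos, dtype=np.int64)
            if chrom.shape != p.shape or pos.shape != p.shape:
                raise ValueError("chrom/pos must match p in length")
            if np.any(pos < 1):
                raise ValueError("pos is 1-based and must be >= 1")
        self.chrom = chrom
        self.pos = pos

    # ------------------------------------------------------------------
    @property
    def L(self) -> int:
        """Number of tests in the family."""
        return self.p.size

    def __len__(self) -> int:
        return self.L

    @property
    def has_coords(self) -> bool:
        return self.chrom is not None

    def subset_weight(self, subset: Subset) -> float:
        """wR: total weight of the subset's members."""
        return float(self.w[np.asarray(subset.indices, dtype=np.intp)].sum())

    def check_subset(self, subset: Subset) -> np.ndarray:
        idx = np.asarray(subset.indices, dtype=np.intp)
        if idx.max() >= self.L:
            raise IndexError(
                f"subset index {idx.max()} out of bounds for family of {self.L}"
            )
        return idx

    def full_subset(self, label: str = "ALL") -> Subset:
        """The degenerate subset covering the whole family."""
        return Subset(indices=tuple(range(self.L)), label=label)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "WeightedPValues":
        """Build from a DataFrame with column ``p`` and optional
        ``w``, ``id``, ``chrom``, ``pos``."""
        if "p" not in df.columns:
            raise ValueError("input table must contain a 'p' column")
        kw = {}
        if "w" in df.columns:
            kw["w"] = df["w"].to_numpy(dtype=float)
        if "id" in df.columns:
            kw["ids"] = df["id"].astype(str).tolist()
        if "chrom" in df.columns or "pos" in df.columns:
            if not {"chrom", "pos"} <= set(df.columns):
                raise ValueError("chrom and pos columns must appear together")
            kw["chrom"] = df["chrom"].astype(str).to_numpy(dtype=object)
            kw["pos"] = df["pos"].to_numpy(dtype=np.int64)
        return cls(df["p"].to_numpy(dtype=float), **kw)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"p": self.p, "w": self.w}
        if self.ids is not None:
            data["id"] = self.ids
        if self.has_coords:
            data["chrom"] = self.chrom
            data["pos"] = self.pos
        return pd.DataFrame(data)


def read_pvalues(path, drop_na: bool = True) -> WeightedPValues:
    """Read a TSV of per-test p-values.

    Required column ``p``; optional ``id``, ``w``, ``chrom``, ``pos``
    (1-based).  Rows with missing p-values are dropped with a warning, not
    imputed.
    """
    df = pd.read_csv(path, sep="\t")
    if "p" not in df.columns:
        raise ValueError(f"{path}: no 'p' column in header {list(df.columns)}")
    n_na = int(df["p"].isna().sum())
    if n_na:
        if not drop_na:
            raise ValueError(f"{path}: {n_na} missing p-values")
        warnings.warn(f"{path}: dropping {n_na} rows with missing p-values")
        df = df.dropna(subset=["p"])
    return WeightedPValues.from_dataframe(df)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a per-subset results table as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
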