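"""Region-based scanning of per-variant p-values over nested genomic windows.

Mirrors the GWAS usage pattern: per-variant association p-values are combined
by the HMP over sliding windows of several sizes (default 10 kb, 100 kb,
1 Mb, 10 Mb), over whole chromosomes, and over the whole genome.  Each
window's combined p-value is adjusted by the inverse subset weight so that
every level can be read against the single threshold alpha; under equal
weights wR is simply (number of member variants)/L, so smaller windows
automatically face proportionally stricter unadjusted thresholds.

Coordinates are half-open [start, end), 0-based internally, 1-based in all
input/output.  Windows overlap by default (step = size/2); edge windows are
truncated to the observed chromosome bounds.  Empty windows are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import HMPResult, _subset_result
from .pvalues import Subset, WeightedPValues

__all__ = [
    "WindowSpec",
    "scan_windows",
    "bonferroni_threshold",
    "results_to_bed",
    "make_fixture",
]

_DEFAULT_SIZES = (10_000, 100_000, 1_000_000, 10_000_000)


@dataclass(frozen=True)
class WindowSpec:
    """Window sizes (bp) and stepping for a multi-level scan.

    ``step_fraction`` of 0.5 gives half-overlapping windows; 1.0 gives
    non-overlapping tiles.  Chromosome and genome levels are always
    included on top of the base-pair sizes.
    """

    sizes: Sequence[int] = _DEFAULT_SIZES
    step_fraction: float = 0.5

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("window sizes must be positive")
        if list(sizes) != sorted(set(sizes)):
            raise ValueError("window sizes must be strictly increasing")
        if not (0.0 < self.step_fraction <= 1.0):
            raise ValueError("step_fraction must be in (0, 1]")
        object.__setattr__(self, "sizes", sizes)


def bonferroni_threshold(L: int, alpha: float = 0.05) -> float:
    """Per-test Bonferroni cutoff alpha / L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / L


def _result_row(r: HMPResult, level: str) -> dict:
    chrom, start, end = r.interval if r.interval else (None, None, None)
    return {
        "level": level,
        "label": r.label,
        "chrom": chrom,
        "start": start,
        "end": end,
        "n": r.n,
        "wR": r.wR,
        "hmp": r.hmp,
        "adjusted": r.adjusted,
        "exact_p": r.exact_p,
        "neglog10_adjusted": float(-np.log10(r.adjusted)),
        "significant": r.significant,
    }


def scan_windows(
    pv: WeightedPValues,
    spec: WindowSpec = WindowSpec(),
    alpha: float = 0.05,
    method: str = "exact",
) -> pd.DataFrame:
    """Combine per-variant p-values over nested windows at every level.

    Requires coordinates, sorted by position within each chromosome.  Returns
    one row per non-empty window plus per-chromosome rows and a genome-level
    headline row labeled ``GENOME``; the significant flag compares each
    region at its own threshold ``alpha * wR`` (via the requested method).
    """
    if not pv.has_coords:
        raise ValueError("scan_windows requires chrom/pos coordinates")
    if method not in ("direct", "exact"):
        raise ValueError(f"method must be 'direct' or 'exact', got {method!r}")
    chroms = pd.unique(pv.chrom)
    for c in chroms:
        where = np.flatnonzero(pv.chrom == c)
        pos = pv.pos[where]
        if np.any(np.diff(pos) < 0):
            bad = where[int(np.flatnonzero(np.diff(pos) < 0)[0]) + 1]
            raise ValueError(
                f"positions not sorted within chromosome {c!r} at row {bad} "
                f"(pos {pv.pos[bad]})"
            )

    rows = []
    for c in chroms:
        idx = np.flatnonzero(pv.chrom == c)
        pos0 = pv.pos[idx] - 1  # 0-based
        lo, hi = int(pos0[0]), int(pos0[-1]) + 1
        for size in spec.sizes:
            step = max(1, int(round(size * spec.step_fraction)))
            start = (lo // step) * step
            for ws in range(start, hi, step):
                we = ws + size
                a, b = np.searchsorted(pos0, [ws, we])
                if a == b:
                    continue  # empty window
                sub = Subset(
                    indices=tuple(idx[a:b]),
                    label=f"{c}:{ws + 1}-{we}",
                    interval=(str(c), int(ws), int(we)),
                )
                r = _subset_result(pv, sub, alpha, method)
                rows.append(_result_row(r, level=f"{size}bp"))
        chrom_sub = Subset(
            indices=tuple(idx),
            label=str(c),
            interval=(str(c), int(lo), int(hi)),
        )
        rows.append(_result_row(_subset_result(pv, chrom_sub, alpha, method), "chromosome"))

    headline = _subset_result(pv, pv.full_subset(label="GENOME"), alpha, method)
    rows.append(_result_row(headline, "genome"))
    df = pd.DataFrame(rows)

    if method == "direct":
        sig = df["significant"] & (df["level"] != "genome")
        if sig.any() and not bool(df.loc[df["level"] == "genome", "significant"].iloc[0]):
            raise AssertionError("closure violated: a window rejected but the genome did not")
    return df


def results_to_bed(df: pd.DataFrame, path) -> None:
    """Write window results as BED: chrom, start (0-based), end, name, score.

    Score is -log10 of the adjusted HMP, the usual Manhattan-plot quantity.
    Chromosome/genome-level rows without intervals are skipped.
    """
    bed = df.dropna(subset=["chrom", "start", "end"])
    out = bed.assign(
        start=bed["start"].astype(int),
        end=bed["end"].astype(int),
        score=bed["neglog10_adjusted"].round(4),
    )[["chrom", "start", "end", "label", "score"]]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(
    kind: str,
    path,
    L: int = 1000,
    n_chrom: int = 2,
    spacing: int = 1000,
    spikes: Optional[dict] = None,
    n_blocks: int = 10,
    block_rho: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a deterministic TSV p-value fixture with genomic coordinates.

    kind
        ``'null'`` — iid Uniform(0,1] p-values;
        ``'spiked'`` — null plus planted p-values from ``spikes``, a mapping
        ``{(chrom, pos): p}``;
        ``'correlated-blocks'`` — ``n_blocks`` equicorrelated blocks per
        chromosome (latent Gaussian correlation ``block_rho`` within block).
    """
    if kind not in ("null", "spiked", "correlated-blocks"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    per = L // n_chrom
    counts = [per + (1 if i < L % n_chrom else 0) for i in range(n_chrom)]
    chroms, positions = [], []
    for i, n in enumerate(counts):
        chroms += [f"chr{i + 1}"] * n
        positions += list(np.arange(1, n + 1) * spacing)
    chrom = np.array(chroms, dtype=object)
    pos = np.array(positions, dtype=np.int64)

    if kind == "correlated-blocks":
        from scipy import stats as _st

        p = np.empty(L)
        offset = 0
        for n in counts:
            block_sizes = np.array_split(np.arange(n), n_blocks)
            for blk in block_sizes:
                if blk.size == 0:
                    continue
                shared = rng.standard_normal()
                z = np.sqrt(block_rho) * shared + np.sqrt(1 - block_rho) * rng.standard_normal(blk.size)
                p[offset + blk] = _st.norm.sf(z)
            offset += n
    else:
        p = rng.random(L)
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)

    if kind == "spiked":
        spikes = spikes or {}
        keyed = {(str(c), int(q)): v for (c, q), v in spikes.items()}
        for i in range(L):
            key = (str(chrom[i]), int(pos[i]))
            if key in keyed:
                p[i] = keyed[key]
        missing = set(keyed) - {(str(chrom[i]), int(pos[i])) for i in range(L)}
        if missing:
            raise ValueError(f"spike positions not on the variant grid: {sorted(missing)}")

    df = pd.DataFrame(
        {"id": [f"v{i}" for i in range(L)], "chrom": chrom, "pos": pos, "p": p}
    )
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"could not write fixture to {path}: {exc}") from exc
    return df
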