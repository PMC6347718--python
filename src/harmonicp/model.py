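"""Model/Results interface for harmonic-mean-p-value analyses.

:class:`HarmonicMeanP` wraps a family of p-values (with optional weights and
genomic coordinates) the way a statsmodels model wraps data; ``fit`` runs
the combined test — over the whole family, over named subsets, or over a
genomic window scan — and returns an :class:`HMPResults` with the headline
statistic, per-subset table, and a ``summary()``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import core
from .landau import threshold
from .pvalues import Subset, WeightedPValues, read_pvalues
from .windows import WindowSpec, scan_windows

__all__ = ["HarmonicMeanP", "HMPResults"]


class HarmonicMeanP:
    """Combined test of a family of L p-values via the harmonic mean.

    Parameters as for :class:`~harmonicp.pvalues.WeightedPValues`; see
    :meth:`from_dataframe` and :meth:`from_tsv` for tabular construction.

    Examples
    --------
    >>> import numpy as np
    >>> from harmonicp import HarmonicMeanP
    >>> res = HarmonicMeanP(np.array([1e-4, 0.2, 0.7, 0.9])).fit(alpha=0.05)
    >>> bool(res.significant)
    True
    """

    def __init__(self, p, w=None, ids=None, chrom=None, pos=None):
        if isinstance(p, WeightedPValues):
            self.data = p
        else:
            self.data = WeightedPValues(p, w=w, ids=ids, chrom=chrom, pos=pos)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HarmonicMeanP":
        return cls(WeightedPValues.from_dataframe(df))

    @classmethod
    def from_tsv(cls, path) -> "HarmonicMeanP":
        return cls(read_pvalues(path))

    @property
    def L(self) -> int:
        return self.data.L

    def fit(
        self,
        alpha: float = 0.05,
        method: str = "exact",
        subsets: Optional[Sequence[Subset]] = None,
        windows: Optional[WindowSpec] = None,
    ) -> "HMPResults":
        """Run the combined test and return results.

        ``method`` is ``'exact'`` (asymptotically exact Landau-tail test,
        recommended) or ``'direct'`` (compare the HMP itself with
        ``alpha * wR``).  ``subsets`` adds named subset tests; ``windows``
        runs a genomic window scan (requires coordinates).  The headline
        test over all L p-values is always computed.
        """
        scan = None
        if windows is not None:
            scan = scan_windows(self.data, windows, alpha=alpha, method=method)
        headline, subset_results = core.multilevel_test(
            self.data, subsets or [], alpha=alpha, method=method
        )
        return HMPResults(
            model=self,
            headline=headline,
            subset_results=list(subset_results),
            scan=scan,
            alpha=alpha,
            method=method,
        )


class HMPResults:
    """Results of a harmonic-mean-p-value analysis.

    Attributes
    ----------
    headline : HMPResult
        Whole-family combined test.
    subset_results : list of HMPResult
        Per-subset tests at thresholds ``alpha * wR``.
    scan : DataFrame or None
        Window-scan table when a :class:`WindowSpec` was given.
    """

    def __init__(self, model, headline, subset_results, scan, alpha, method):
        self.model = model
        self.headline = headline
        self.subset_results = subset_results
        self.scan = scan
        self.alpha = alpha
        self.method = method

    # -- headline conveniences ------------------------------------------
    @property
    def hmp(self) -> float:
        return self.headline.hmp

    @property
    def exact_p(self):
        return self.headline.exact_p

    @property
    def significant(self) -> bool:
        return self.headline.significant

    @property
    def pvalue(self) -> float:
        """Headline p-value on the family scale: exact when available."""
        return self.exact_p if self.exact_p is not None else self.hmp

    def model_posteriors(self, subset: Optional[Subset] = None) -> np.ndarray:
        """Approximate posterior model probabilities over a subset's members."""
        return core.model_posteriors(self.model.data, subset)

    def comparators(self) -> dict:
        """Bonferroni/Simes/BH/Fisher comparator results on the same family."""
        return core.comparator_tests(self.model.data, self.alpha)

    def to_frame(self) -> pd.DataFrame:
        """Headline + subset results as a tidy table."""
        rows = []
        for r in [self.headline] + self.subset_results:
            rows.append(
                {
                    "label": r.label or "ALL",
                    "n": r.n,
                    "wR": r.wR,
                    "hmp": r.hmp,
                    "adjusted": r.adjusted,
                    "exact_p": r.exact_p,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table."""
        h = self.headline
        lines = [
            "Harmonic mean p-value results",
            "=" * 64,
            f"Tests (L):            {h.L_total}",
            f"Method:               {self.method}",
            f"FWER level alpha:     {self.alpha:g}",
            f"Headline HMP:         {h.hmp:.6g}",
        ]
        if h.exact_p is not None:
            lines.append(f"Asymptotically exact p: {h.exact_p:.6g}")
            lines.append(
                f"Adjusted-HMP threshold alpha_|R|: "
                f"{threshold(h.L_total, self.alpha):.4g}"
            )
        lines.append(f"Headline significant: {h.significant}")
        if self.subset_results:
            lines.append("-" * 64)
            lines.append(self.to_frame().to_string(index=False))
        if self.scan is not None:
            n_sig = int(self.scan["significant"].sum())
            lines.append("-" * 64)
            lines.append(
                f"Window scan: {len(self.scan)} regions, {n_sig} significant"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<HMPResults L={self.headline.L_total} hmp={self.hmp:.4g} "
            f"significant={self.significant}>"
        )
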