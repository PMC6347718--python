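"""The weighted harmonic mean p-value and its significance tests.

The HMP of a subset R of a family of L p-values with weights summing to one
over the family is

    p°R = (sum_{i in R} w_i) / (sum_{i in R} w_i / p_i).

Two tests are provided, both controlling the strong-sense familywise error
rate across arbitrarily many (possibly overlapping) subsets:

* the *direct* test rejects when ``p°R <= alpha * wR`` — simple, and valid
  because the HMP is asymptotically well calibrated for small values, but
  very slightly anticonservative;
* the *asymptotically exact* test compares the Landau tail probability of
  ``1/p°R`` (location ``log L + 0.874``, scale ``pi/2``) against
  ``alpha * wR``, equivalently the adjusted HMP ``p°R / wR`` against the
  inverted-threshold ``alpha_|R|``.  This is the recommended default.

The multilevel structure is closed under subsetting: a rejected subset
implies the whole-family ("headline") HMP is itself significant, so any
number of subsets may be examined without further correction.

Comparator combined tests (Bonferroni, Simes, Benjamini–Hochberg, Fisher)
are included for power/FWER benchmarking; they ignore weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .landau import hmp_null, threshold
from .pvalues import Subset, WeightedPValues

__all__ = [
    "HMPResult",
    "harmonic_mean_p",
    "mean_max_lr",
    "model_posteriors",
    "direct_test",
    "exact_test",
    "multilevel_test",
    "bonferroni_combined",
    "simes_combined",
    "fisher_combined",
    "bh_rejections",
    "comparator_tests",
]

_ALPHA_WARN_LEVEL = 0.05


@dataclass(frozen=True)
class HMPResult:
    """Outcome of testing one subset R of a p-value family.

    Attributes
    ----------
    hmp : float
        The harmonic mean p-value p°R, in (0, 1].
    adjusted : float
        p°R / wR, directly comparable with the family-level alpha (or with
        the stricter threshold alpha_|R| under the exact test).
    exact_p : float or None
        Asymptotically exact p-value: Landau tail probability of 1/p°R.
        None when only the direct test was requested.
    wR : float
        Subset weight, sum of member weights.
    L_total : int
        Number of tests in the full family (sets the Landau location).
    alpha : float
        Nominal strong-sense FWER level.
    significant_direct : bool
        Direct-interpretation decision, p°R <= alpha * wR (boundary rejects).
    significant_exact : bool or None
        Exact-test decision, exact_p <= alpha * wR.
    n : int
        Subset size |R|.
    label, interval
        Carried through from the subset, if any.
    """

    hmp: float
    adjusted: float
    wR: float
    L_total: int
    alpha: float
    significant_direct: bool
    n: int
    exact_p: Optional[float] = None
    significant_exact: Optional[bool] = None
    label: Optional[str] = None
    interval: Optional[tuple] = None

    @property
    def significant(self) -> bool:
        """Decision of the preferred test (exact when available)."""
        return (
            self.significant_exact
            if self.significant_exact is not None
            else self.significant_direct
        )


def _validate_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if alpha > _ALPHA_WARN_LEVEL:
        warnings.warn(
            f"alpha={alpha:g} exceeds 0.05; the FWER guarantee of the HMP "
            "is stated for levels of about 0.05 and below",
            UserWarning,
        )


def harmonic_mean_p(pv: WeightedPValues, subset: Optional[Subset] = None) -> float:
    """Weighted harmonic mean p-value of a subset (default: whole family).

    Returns ``(sum_{i in R} w_i) / (sum_{i in R} w_i / p_i)``.  With equal
    weights this is the plain harmonic mean.  Computed through the
    inverse-p sum, which stays finite for p-values down to the smallest
    positive normal double.
    """
    if subset is None:
        idx = slice(None)
        wR = 1.0
    else:
        idx = pv.check_subset(subset)
        wR = pv.subset_weight(subset)
    inv_sum = float(np.sum(pv.w[idx] / pv.p[idx]))
    if inv_sum <= 0.0:
        # all member weights zero: statistic undefined
        raise ValueError("subset carries zero total weight")
    return wR / inv_sum


def mean_max_lr(R, w=None) -> float:
    """Weighted arithmetic mean of maximized likelihood ratios, R̄ = Σ w_i R_i.

    For two-degree-of-freedom likelihood-ratio tests the null p-value equals
    the inverse maximized likelihood ratio, so with ``R_i = 1/p_i`` this
    equals ``1 / harmonic_mean_p`` exactly.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 1 or R.size == 0:
        raise ValueError("R must be a non-empty 1-d vector")
    if np.any(~np.isfinite(R)) or np.any(R <= 0.0):
        raise ValueError("maximized likelihood ratios must be positive and finite")
    if w is None:
        return float(R.mean())
    w = np.asarray(w, dtype=float)
    if w.shape != R.shape or np.any(w < 0.0):
        raise ValueError("weights must be non-negative and match R in length")
    total = w.sum()
    if total <= 0.0:
        raise ValueError("at least one weight must be positive")
    return float(np.dot(w / total, R))


def model_posteriors(pv: WeightedPValues, subset: Optional[Subset] = None) -> np.ndarray:
    """Approximate posterior model probabilities over the members of R.

    Conditional on rejecting the shared null, the Bayes factor of alternative
    i is approximately proportional to the weighted inverse p-value, so the
    normalized probabilities are ``q_i = (w_i/p_i) / sum_{j in R} (w_j/p_j)``.
    Returned in the order of ``subset.indices`` (or family order).
    """
    idx = slice(None) if subset is None else pv.check_subset(subset)
    contrib = pv.w[idx] / pv.p[idx]
    total = contrib.sum()
    if total <= 0.0:
        raise ValueError("subset carries zero total weight")
    return contrib / total


# ---------------------------------------------------------------------------
# decisions


def direct_test(hmp: float, wR: float = 1.0, alpha: float = 0.05) -> bool:
    """Direct interpretation of the HMP: reject iff ``hmp <= alpha * wR``.

    The boundary counts as rejection.  Approximate: very slightly
    anticonservative for small alpha.
    """
    _validate_alpha(alpha)
    if not (0.0 < wR <= 1.0 + 1e-12):
        raise ValueError(f"wR must be in (0, 1], got {wR}")
    if not (0.0 < hmp <= 1.0):
        raise ValueError(f"hmp must be in (0, 1], got {hmp}")
    return hmp <= alpha * wR


def exact_test(
    hmp: float,
    L: int,
    wR: float = 1.0,
    alpha: float = 0.05,
    n: Optional[int] = None,
    label: Optional[str] = None,
    interval: Optional[tuple] = None,
) -> HMPResult:
    """Asymptotically exact HMP test from the Landau null of the inverse HMP.

    ``exact_p`` is the tail probability of the Landau distribution with
    location ``log L + 0.874`` and scale ``pi/2`` at ``1/hmp``; the subset is
    rejected when ``exact_p <= alpha * wR``.  The equivalent formulation —
    adjusted HMP against the inverted threshold alpha_|R| — agrees on every
    input and is used by the vectorized simulation harness.
    """
    _validate_alpha(alpha)
    if not (0.0 < hmp <= 1.0):
        raise ValueError(f"hmp must be in (0, 1], got {hmp}")
    if not (0.0 < wR <= 1.0 + 1e-12):
        raise ValueError(f"wR must be in (0, 1], got {wR}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    exact_p = float(hmp_null(int(L)).sf(1.0 / hmp))
    return HMPResult(
        hmp=hmp,
        adjusted=hmp / wR,
        exact_p=exact_p,
        wR=wR,
        L_total=int(L),
        alpha=alpha,
        significant_direct=hmp <= alpha * wR,
        significant_exact=exact_p <= alpha * wR,
        n=int(n if n is not None else L),
        label=label,
        interval=interval,
    )


def _subset_result(
    pv: WeightedPValues,
    subset: Subset,
    alpha: float,
    method: str,
) -> HMPResult:
    hmp = harmonic_mean_p(pv, subset)
    wR = pv.subset_weight(subset)
    if method == "exact":
        return exact_test(
            hmp, pv.L, wR=wR, alpha=alpha, n=len(subset),
            label=subset.label, interval=subset.interval,
        )
    return HMPResult(
        hmp=hmp,
        adjusted=hmp / wR,
        wR=wR,
        L_total=pv.L,
        alpha=alpha,
        significant_direct=hmp <= alpha * wR,
        n=len(subset),
        label=subset.label,
        interval=subset.interval,
    )


def multilevel_test(
    pv: WeightedPValues,
    subsets: Sequence[Subset],
    alpha: float = 0.05,
    method: str = "exact",
):
    """Test any number of (possibly overlapping) subsets plus the headline.

    Returns ``(headline, results)``: the whole-family :class:`HMPResult` and
    one result per subset at its threshold ``alpha * wR``.  With
    ``method='direct'`` the closure guarantee — a rejected subset implies the
    headline rejects — is asserted internally; with ``method='exact'`` the
    headline is evaluated and reported alongside.
    """
    if method not in ("direct", "exact"):
        raise ValueError(f"method must be 'direct' or 'exact', got {method!r}")
    _validate_alpha(alpha)
    headline = _subset_result(pv, pv.full_subset(), alpha, method)
    results = [_subset_result(pv, s, alpha, method) for s in subsets]
    if method == "direct":
        for r in results:
            if r.significant_direct and not headline.significant_direct:
                raise AssertionError(
                    "closure violated: subset rejected but headline did not "
                    f"(subset {r.label!r}, hmp={r.hmp:g}, headline={headline.hmp:g})"
                )
    return headline, results


# ---------------------------------------------------------------------------
# comparator combined tests (unweighted)


def bonferroni_combined(p) -> float:
    """Bonferroni combined statistic, ``min(1, L * min p)``."""
    p = np.asarray(p, dtype=float)
    return float(min(1.0, p.size * p.min()))


def simes_combined(p) -> float:
    """Simes combined statistic, ``min_k (L/k) * p_(k)``."""
    p = np.sort(np.asarray(p, dtype=float))
    L = p.size
    return float(min(1.0, (p * L / np.arange(1, L + 1)).min()))


def fisher_combined(p) -> float:
    """Fisher's combined p-value: ``-2 * sum log p`` against chi2(2L)."""
    p = np.asarray(p, dtype=float)
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, df=2 * p.size))


def bh_rejections(p, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection set (indices into p) at level alpha."""
    p = np.asarray(p, dtype=float)
    L = p.size
    order = np.argsort(p)
    thresh = alpha * np.arange(1, L + 1) / L
    below = p[order] <= thresh
    if not below.any():
        return np.empty(0, dtype=np.intp)
    k = int(np.flatnonzero(below).max())
    return np.sort(order[: k + 1])


def comparator_tests(pv: WeightedPValues, alpha: float = 0.05) -> dict:
    """Standard comparator methods on the family's p-values.

    Weights are ignored (the classical forms are unweighted).  Returns, per
    method, the combined statistic (or rejection set for BH) and a
    family-level decision at ``alpha``.
    """
    _validate_alpha(alpha)
    p = pv.p
    bon = bonferroni_combined(p)
    sim = simes_combined(p)
    fis = fisher_combined(p)
    bh = bh_rejections(p, alpha)
    return {
        "bonferroni": {"statistic": bon, "reject": bon <= alpha},
        "simes": {"statistic": sim, "reject": sim <= alpha},
        "fisher": {"statistic": fis, "reject": fis <= alpha},
        "bh": {"rejections": bh, "reject": bh.size > 0},
    }
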