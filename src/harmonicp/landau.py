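"""Numerics for the Landau distribution null of the inverse harmonic mean p-value.

The harmonic mean p-value (HMP) of L well-calibrated p-values has, under the
global null, an inverse 1/p° whose distribution converges (by the generalized
central limit theorem for heavy-tailed summands) to a Landau distribution —
the maximally skewed stable law with stability index 1 — with location
``mu = log(L) + 0.874`` (natural log) and scale ``sigma = pi/2``.

This module evaluates the Landau density, tail probability, and quantiles
from the integral representation

    f(x | mu, sigma) = 1/(pi*sigma) * int_0^inf
        exp(-t*(x-mu)/sigma - (2/pi)*t*log(t)) * sin(2*t) dt

and provides the adjusted-HMP significance thresholds obtained by inverting
the tail probability.

Numerical strategy, in standardized units ``s = (x - mu)/sigma``:

* density: lobe-by-lobe adaptive quadrature between consecutive zeros of
  ``sin(2t)`` for ``s >= -2.4``; a saddle-point asymptotic
  ``(1/2)*sqrt(rho)*exp(-(2/pi)*rho)*(1 + pi/(48*rho))`` with
  ``rho = exp(-pi*s/2 - 1)`` in the far left tail, where the real-axis
  integral cancels catastrophically.
* survival function: the density integral can be integrated in closed form
  over x, giving ``sf = (1/pi) * int_0^inf exp(-t*s - (2/pi)*t*log(t))
  * sin(2t)/t dt``.  For ``s > 3`` the substitution ``u = t*s`` removes the
  oscillation; for ``-3 < s <= 3`` the lobe sum is used; for ``s <= -3``
  the asymptotic ``1 - exp(-(2/pi)*rho)/(2*sqrt(rho))``.
* quantiles: Brent root-finding on the survival function, bracketed by the
  stability-index-1 tail expansion ``sf(x) ~ (2*sigma/pi)/(x - mu)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

__all__ = [
    "LandauDistribution",
    "hmp_null",
    "threshold",
    "threshold_table",
    "HMP_LOCATION_OFFSET",
]

#: Additive constant in the location of the HMP null, mu = log(L) + 0.874.
HMP_LOCATION_OFFSET = 0.874

# Crossover points in standardized units; see module docstring.
_PDF_SADDLE_CROSSOVER = -2.4
_SF_LEFT_CROSSOVER = -3.0
_SF_SMOOTH_CROSSOVER = 3.0
_HALF_PI = np.pi / 2.0


class LandauQuadratureError(ArithmeticError):
    """Raised when quadrature or root-finding for the Landau law fails."""


def _exponent(t: np.ndarray | float, s: float) -> np.ndarray | float:
    """Exponent of the integrand: -t*s - (2/pi)*t*log(t)."""
    return -t * s - (2.0 / np.pi) * t * np.log(t)


def _lobe_sum(integrand, s: float, x: float) -> float:
    """Sum adaptive quadrature over lobes [k*pi/2, (k+1)*pi/2] of sin(2t).

    The envelope exp(-t*s - (2/pi)*t*log(t)) decays super-exponentially in t,
    so the lobe series truncates quickly; alternating lobes partially cancel,
    which is why each lobe is integrated separately.
    """
    total = 0.0
    for k in range(4000):
        a, b = k * _HALF_PI, (k + 1) * _HALF_PI
        try:
            val, _ = integrate.quad(integrand, a, b, limit=200, epsabs=1e-300)
        except Exception as exc:  # pragma: no cover - quad rarely raises
            raise LandauQuadratureError(
                f"Landau quadrature failed on lobe [{a:g}, {b:g}] at x={x:g}"
            ) from exc
        total += val
        if k > 4 and abs(val) < 1e-17 * max(1e-300, abs(total)):
            return total
        # envelope check: once the exponent is far below the running total,
        # remaining lobes are negligible
        if k > 8 and _exponent(b, s) < math.log(max(abs(total), 1e-300)) - 40.0:
            return total
    raise LandauQuadratureError(f"Landau lobe series did not converge at x={x:g}")


def _pdf_standard(s: float) -> float:
    """Standard (mu=0, sigma=1) Landau density at s."""
    if not np.isfinite(s):
        return 0.0
    if s < _PDF_SADDLE_CROSSOVER:
        rho = math.exp(-np.pi * s / 2.0 - 1.0)
        log_f = 0.5 * math.log(rho) - (2.0 / np.pi) * rho + math.log(0.5)
        if log_f < -745.0:  # below smallest positive double
            return 0.0
        return math.exp(log_f) * (1.0 + np.pi / (48.0 * rho))

    def integrand(t: float) -> float:
        if t <= 0.0:
            return 0.0
        return math.exp(_exponent(t, s)) * math.sin(2.0 * t)

    return max(0.0, _lobe_sum(integrand, s, s) / np.pi)


def _sf_standard(s: float) -> float:
    """Standard Landau survival function Pr(X >= s) for mu=0, sigma=1."""
    if not np.isfinite(s):
        return 0.0 if s > 0 else 1.0
    if s <= _SF_LEFT_CROSSOVER:
        rho = math.exp(-np.pi * s / 2.0 - 1.0)
        log_cdf = -(2.0 / np.pi) * rho - 0.5 * math.log(rho) - math.log(2.0)
        cdf = math.exp(log_cdf) if log_cdf > -745.0 else 0.0
        return 1.0 - cdf
    if s > _SF_SMOOTH_CROSSOVER:
        # substitute u = t*s: the sine argument 2u/s stays within a fraction
        # of one period over the e^{-u} decay, so the integrand is smooth
        def integrand(u: float) -> float:
            if u <= 0.0:
                return 2.0 / s
            t = u / s
            return math.exp(-u + _exponent(t, 0.0)) * math.sin(2.0 * t) / (t * s)

        try:
            val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        except Exception as exc:  # pragma: no cover
            raise LandauQuadratureError(
                f"Landau tail quadrature failed at s={s:g}"
            ) from exc
        return min(1.0, max(0.0, val / np.pi))

    def integrand(t: float) -> float:
        if t <= 0.0:
            return 2.0
        return math.exp(_exponent(t, s)) * math.sin(2.0 * t) / t

    return min(1.0, max(0.0, _lobe_sum(integrand, s, s) / np.pi))


@dataclass(frozen=True)
class LandauDistribution:
    """Landau distribution with location ``mu`` and scale ``sigma``.

    For the null distribution of the inverse HMP over ``L`` tests, use
    :func:`hmp_null`, which sets ``mu = log(L) + 0.874`` and
    ``sigma = pi/2``.
    """

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    # -- densities and probabilities -------------------------------------
    def pdf(self, x):
        """Probability density, elementwise over x."""
        xs = np.asarray(x, dtype=float)
        out = np.array(
            [_pdf_standard(si) for si in np.atleast_1d((xs - self.mu) / self.sigma)]
        ) / self.sigma
        return out[0] if xs.ndim == 0 else out.reshape(xs.shape)

    def sf(self, x):
        """Upper tail probability Pr(X >= x), elementwise over x."""
        xs = np.asarray(x, dtype=float)
        out = np.array(
            [_sf_standard(si) for si in np.atleast_1d((xs - self.mu) / self.sigma)]
        )
        return out[0] if xs.ndim == 0 else out.reshape(xs.shape)

    def cdf(self, x):
        return 1.0 - self.sf(x)

    # -- quantiles -------------------------------------------------------
    def isf(self, q: float) -> float:
        """Inverse survival function: x with Pr(X >= x) = q.

        Root-finds on :meth:`sf` with a bracket seeded by the index-1 tail
        expansion ``sf(x) ~ (2*sigma/pi)/(x - mu)``; relative tolerance in
        the tail mass is ~1e-8.
        """
        if not (0.0 < q < 1.0):
            raise ValueError(f"tail mass q must be in (0, 1), got {q}")
        x0 = self.mu + 2.0 * self.sigma / (np.pi * q)
        lo, hi = self.mu - 4.0 * self.sigma, max(x0 * 8.0, self.mu + self.sigma)
        f = lambda x: self.sf(x) - q
        flo, fhi = f(lo), f(hi)
        for _ in range(60):
            if flo > 0.0 >= fhi:
                break
            if flo <= 0.0:
                lo -= 2.0 * self.sigma
                flo = f(lo)
            if fhi > 0.0:
                hi *= 4.0
                fhi = f(hi)
        else:
            raise LandauQuadratureError(f"could not bracket quantile q={q:g}")
        try:
            return optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
        except Exception as exc:  # pragma: no cover
            raise LandauQuadratureError(f"quantile root-find failed at q={q:g}") from exc

    def ppf(self, q: float) -> float:
        """Quantile function (inverse cdf)."""
        return self.isf(1.0 - q)


def hmp_null(L: int) -> LandauDistribution:
    """Null distribution of the inverse HMP of ``L`` well-calibrated p-values."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return LandauDistribution(mu=math.log(L) + HMP_LOCATION_OFFSET, sigma=_HALF_PI)


@lru_cache(maxsize=4096)
def threshold(L: int, alpha: float) -> float:
    """Adjusted-HMP critical value ``alpha_|R|`` for ``L`` tests at FWER ``alpha``.

    The asymptotically exact test rejects a subset R when the adjusted HMP
    ``p°R / wR`` falls at or below this value.  Computed as the reciprocal of
    the Landau ``1 - alpha`` quantile of the HMP null.  Decreases in L and
    increases in alpha; always smaller than alpha itself.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return 1.0 / hmp_null(int(L)).isf(alpha)


def threshold_table(
    Ls: Iterable[int] = (10, 100, 1000, 10**4, 10**5, 10**6, 10**7, 10**8, 10**9),
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
) -> pd.DataFrame:
    """Table of adjusted-HMP significance thresholds, rows |R|, columns alpha."""
    rows = {int(L): [threshold(int(L), a) for a in alphas] for L in Ls}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"alpha={a:g}" for a in alphas]
    ).rename_axis("|R|")
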