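"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: dense fixed-grid
trapezoid quadrature of the Landau integrals, and exact rational arithmetic
for harmonic means.
"""

from fractions import Fraction
from math import floor, log10

import numpy as np


def round_2sf(v: float) -> float:
    """Round to two significant figures, as printed threshold tables do."""
    return round(v, 1 - int(floor(log10(abs(v)))))


def _t_cutoff(s: float, budget: float = 45.0) -> float:
    """Upper integration limit where the envelope exp(-t*s-(2/pi)t*log t)
    has decayed below exp(-budget)."""
    t = 1e-6
    for _ in range(200):
        val = (2.0 / np.pi) * t * np.log(max(t, 1e-12)) + t * s
        if val > budget:
            return t
        t *= 1.25
    return t


def landau_pdf_trapz(x: float, mu: float = 0.0, sigma: float = 1.0,
                     n: int = 2_000_000) -> float:
    """Landau density by dense trapezoid quadrature of the defining integral."""
    s = (x - mu) / sigma
    T = _t_cutoff(min(s, 0.0) if s < 0 else s)
    t = np.linspace(1e-12, T, n)
    f = np.exp(-t * s - (2.0 / np.pi) * t * np.log(t)) * np.sin(2.0 * t)
    return float(np.trapezoid(f, t) / (np.pi * sigma))


def landau_sf_trapz(x: float, mu: float = 0.0, sigma: float = 1.0,
                    n: int = 2_000_000) -> float:
    """Landau upper-tail probability by dense trapezoid quadrature of the
    closed-form survival integrand (density integrated over x analytically)."""
    s = (x - mu) / sigma
    T = _t_cutoff(min(s, 0.0) if s < 0 else s)
    t = np.linspace(1e-12, T, n)
    f = np.exp(-t * s - (2.0 / np.pi) * t * np.log(t)) * np.sin(2.0 * t) / t
    return float(np.trapezoid(f, t) / np.pi)


def hmp_exact_fraction(p, w=None) -> Fraction:
    """Weighted harmonic mean of p-values in exact rational arithmetic."""
    p = [Fraction(x) for x in p]
    if w is None:
        w = [Fraction(1, len(p))] * len(p)
    else:
        w = [Fraction(x) for x in w]
    return sum(w) / sum(wi / pi for wi, pi in zip(w, p))
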