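"""Monte-Carlo harness: null/alternative p-value families and method comparison.

Generators
----------
* Correlated p-values from a single-factor equicorrelated Gaussian copula:
  latent z-scores ``z_i = sqrt(rho) * z0 + sqrt(1-rho) * e_i`` (plus a mean
  shift for true signals), mapped to one-sided p-values ``p = Phi(-z)``.
  At ``rho = 0`` the null p-values are iid Uniform(0, 1).
* Maximized likelihood ratios under a two-degree-of-freedom null:
  ``R = 1/U`` with U uniform, the exact LogGamma(1, 1) law, for which the
  p-value is exactly ``1/R``.  The equal-weight mean of L such draws is the
  heavy-tailed sum whose limit is Landau(log L + 0.874, pi/2).

Experiments
-----------
:func:`estimate_fwer` and :func:`estimate_power` apply each requested method
replicate-by-replicate (vectorized across replicates) and report the
fraction of replicates with a familywise rejection, with a binomial
Monte-Carlo standard error.  For combined tests (HMP variants, Fisher) a
familywise rejection means rejection of the headline null over all L tests;
for per-test procedures (Bonferroni, BH) it means any individual rejection.
All randomness flows from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landau import hmp_null, threshold

__all__ = [
    "SimulationScenario",
    "SimulationSummary",
    "generate_null_pvalues",
    "generate_pvalues",
    "generate_loggamma_lrs",
    "estimate_fwer",
    "estimate_power",
    "METHODS",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Settings for one Monte-Carlo experiment.

    Parameters
    ----------
    L : int
        Number of tests per family.
    rho : float
        Equicorrelation of the latent Gaussian test statistics, in [0, 1).
    n_signals : int
        Number of true alternatives (0 for a null / FWER scenario).
    effect : float
        Mean shift of the latent z-score under each alternative.
    alpha : float
        Nominal FWER level.
    reps : int
        Monte-Carlo replicates.
    seed : int
        Mandatory RNG seed; there is no implicit randomness.
    """

    L: int
    rho: float = 0.0
    n_signals: int = 0
    effect: float = 0.0
    alpha: float = 0.05
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0 <= self.n_signals <= self.L):
            raise ValueError("n_signals must be in [0, L]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class SimulationSummary:
    """Per-method FWER or power estimates with Monte-Carlo standard errors."""

    kind: str  # "fwer" or "power"
    scenario: SimulationScenario
    estimates: pd.DataFrame = field(repr=False)

    def __str__(self) -> str:  # pragma: no cover - display helper
        head = (
            f"{self.kind.upper()} estimates "
            f"(L={self.scenario.L}, rho={self.scenario.rho:g}, "
            f"n_signals={self.scenario.n_signals}, effect={self.scenario.effect:g}, "
            f"alpha={self.scenario.alpha:g}, reps={self.scenario.reps}, "
            f"seed={self.scenario.seed})"
        )
        return head + "\n" + self.estimates.to_string(index=False)


def generate_pvalues(scenario: SimulationScenario) -> np.ndarray:
    """Matrix of p-values (reps x L) from the equicorrelated Gaussian copula.

    The first ``n_signals`` columns carry the mean shift ``effect``.
    """
    rng = np.random.default_rng(scenario.seed)
    reps, L, rho = scenario.reps, scenario.L, scenario.rho
    shared = rng.standard_normal((reps, 1))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((reps, L))
    if scenario.n_signals:
        z[:, : scenario.n_signals] += scenario.effect
    p = stats.norm.sf(z)
    # guard against underflow to exactly 0 for extreme effects
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    return p


def generate_null_pvalues(scenario: SimulationScenario) -> np.ndarray:
    """Null p-value matrix: the copula generator with no signals."""
    if scenario.n_signals != 0:
        scenario = replace(scenario, n_signals=0, effect=0.0)
    return generate_pvalues(scenario)


def generate_loggamma_lrs(L: int, reps: int, seed: int) -> np.ndarray:
    """Matrix (reps x L) of null maximized likelihood ratios R = 1/U.

    This is the LogGamma(1, 1) law of a two-degree-of-freedom likelihood
    ratio: Pr(R > r) = 1/r for r >= 1, and the test's p-value is 1/R.
    """
    if L < 1 or reps < 1:
        raise ValueError("L and reps must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((reps, L))
    np.clip(u, np.finfo(float).tiny, None, out=u)
    return 1.0 / u


# ---------------------------------------------------------------------------
# vectorized per-replicate familywise decisions


def _hmp_rows(p: np.ndarray) -> np.ndarray:
    """Equal-weight HMP of each row."""
    L = p.shape[1]
    return L / np.sum(1.0 / p, axis=1)


def _reject_hmp_direct(p: np.ndarray, alpha: float) -> np.ndarray:
    return _hmp_rows(p) <= alpha


def _reject_hmp_exact(p: np.ndarray, alpha: float) -> np.ndarray:
    # threshold formulation of the exact test: adjusted HMP vs alpha_|R|
    return _hmp_rows(p) <= threshold(p.shape[1], alpha)


def _reject_bonferroni(p: np.ndarray, alpha: float) -> np.ndarray:
    return p.min(axis=1) <= alpha / p.shape[1]


def _reject_simes(p: np.ndarray, alpha: float) -> np.ndarray:
    L = p.shape[1]
    ranks = np.arange(1, L + 1)
    stat = (np.sort(p, axis=1) * L / ranks).min(axis=1)
    return stat <= alpha


def _reject_bh(p: np.ndarray, alpha: float) -> np.ndarray:
    # BH makes >= 1 rejection iff the Simes statistic is <= alpha
    return _reject_simes(p, alpha)


def _reject_fisher(p: np.ndarray, alpha: float) -> np.ndarray:
    stat = -2.0 * np.log(p).sum(axis=1)
    return stats.chi2.sf(stat, df=2 * p.shape[1]) <= alpha


METHODS = {
    "hmp_direct": _reject_hmp_direct,
    "hmp_exact": _reject_hmp_exact,
    "bonferroni": _reject_bonferroni,
    "simes": _reject_simes,
    "bh": _reject_bh,
    "fisher": _reject_fisher,
}


def _run(scenario: SimulationScenario, methods: Sequence[str], kind: str) -> SimulationSummary:
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {sorted(METHODS)}")
    p = generate_pvalues(scenario)
    rows = []
    for name in methods:
        est = float(METHODS[name](p, scenario.alpha).mean())
        se = float(np.sqrt(est * (1.0 - est) / scenario.reps))
        rows.append({"method": name, "estimate": est, "se": se})
    return SimulationSummary(kind=kind, scenario=scenario, estimates=pd.DataFrame(rows))


def estimate_fwer(
    scenario: SimulationScenario, methods: Sequence[str] = tuple(METHODS)
) -> SimulationSummary:
    """Familywise error rate under the scenario's null (requires n_signals=0)."""
    if scenario.n_signals != 0:
        raise ValueError("FWER estimation requires n_signals = 0")
    return _run(scenario, methods, "fwer")


def estimate_power(
    scenario: SimulationScenario, methods: Sequence[str] = tuple(METHODS)
) -> SimulationSummary:
    """Familywise power (probability of any rejection) under the alternative."""
    if scenario.n_signals < 1:
        raise ValueError("power estimation requires n_signals >= 1")
    return _run(scenario, methods, "power")
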