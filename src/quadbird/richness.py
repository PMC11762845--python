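"""Total-richness estimation and sampling completeness.

Given a species x quadrat incidence matrix, four nonparametric estimators of
the total species pool are provided: Chao1, first- and second-order
jackknife (all driven by the singleton/doubleton frequency counts), and the
Michaelis-Menten asymptote fitted to a resampled species-accumulation curve
via the Eadie-Hofstee linearization.  Sampling completeness is the observed
richness divided by the estimate, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class Estimator(str, Enum):
    CHAO1 = "chao1"
    JACKKNIFE1 = "jackknife1"
    JACKKNIFE2 = "jackknife2"
    MICHAELIS_MENTEN = "michaelis_menten"


@dataclass(frozen=True)
class FrequencyCounts:
    """Observed richness and singleton/doubleton counts over n quadrats."""

    s_obs: int
    f1: int  # species occurring in exactly one quadrat
    f2: int  # species occurring in exactly two quadrats
    n: int  # quadrats sampled

    def __post_init__(self):
        if min(self.s_obs, self.f1, self.f2) < 0 or self.n < 1:
            raise ValueError("counts must be nonnegative and n >= 1")
        if self.f1 + self.f2 > self.s_obs:
            raise ValueError("f1 + f2 cannot exceed s_obs")


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean species count after t quadrats, averaged over random orderings."""

    t: np.ndarray  # 1..n
    s_mean: np.ndarray
    iterations: int
    seed: int


@dataclass(frozen=True)
class RichnessEstimate:
    estimator: Estimator
    s_hat: float
    completeness_pct: float | None = None


class EstimationError(RuntimeError):
    """Degenerate input for which the estimator is undefined."""


def frequency_counts(inc: np.ndarray) -> FrequencyCounts:
    """Tally s_obs, singletons and doubletons from an incidence matrix.

    Species with zero occurrences are excluded from ``s_obs``.
    """
    inc = np.asarray(inc)
    if not np.isin(inc, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    occ = inc.sum(axis=1)
    return FrequencyCounts(
        s_obs=int((occ >= 1).sum()),
        f1=int((occ == 1).sum()),
        f2=int((occ == 2).sum()),
        n=int(inc.shape[1]),
    )


def chao1(c: FrequencyCounts) -> RichnessEstimate:
    """Chao's lower-bound estimator, S_obs + f1^2 / (2 f2).

    When no doubletons exist the classic form is undefined; the
    bias-corrected fallback S_obs + f1 (f1 - 1) / 2 is used instead.
    """
    if c.f2 > 0:
        s_hat = c.s_obs + c.f1**2 / (2.0 * c.f2)
    else:
        s_hat = c.s_obs + c.f1 * (c.f1 - 1) / 2.0
    return RichnessEstimate(Estimator.CHAO1, float(s_hat))


def jackknife1(c: FrequencyCounts) -> RichnessEstimate:
    """First-order jackknife: S_obs + f1 (n-1)/n."""
    if c.n < 2:
        raise EstimationError("first-order jackknife needs n >= 2 quadrats")
    s_hat = c.s_obs + c.f1 * (c.n - 1) / c.n
    return RichnessEstimate(Estimator.JACKKNIFE1, float(s_hat))


def jackknife2(c: FrequencyCounts) -> RichnessEstimate:
    """Second-order jackknife: S_obs + f1 (2n-3)/n - f2 (n-2)^2 / (n (n-1))."""
    if c.n < 3:
        raise EstimationError("second-order jackknife needs n >= 3 quadrats")
    s_hat = (
        c.s_obs
        + c.f1 * (2 * c.n - 3) / c.n
        - c.f2 * (c.n - 2) ** 2 / (c.n * (c.n - 1))
    )
    return RichnessEstimate(Estimator.JACKKNIFE2, float(s_hat))


def accumulation_curve(
    inc: np.ndarray, iterations: int = 10_000, seed: int = 0
) -> AccumulationCurve:
    """Species-accumulation curve averaged over random quadrat orderings.

    Resampling the ordering (default 10^4 iterations) removes the dependence
    of the raw curve on the arbitrary order in which quadrats were visited.
    The curve is monotone nondecreasing and ends exactly at the observed
    richness.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    inc = np.asarray(inc).astype(bool)
    s, n = inc.shape
    rng = np.random.default_rng(seed)
    totals = np.zeros(n, dtype=np.float64)
    for _ in range(iterations):
        order = rng.permutation(n)
        # cumulative union of species along the ordering
        seen = np.cumsum(inc[:, order], axis=1) >= 1
        totals += seen.sum(axis=0)
    s_mean = totals / iterations
    # the full-sample point is order-invariant: pin it exactly
    s_mean[-1] = float((inc.sum(axis=1) >= 1).sum())
    return AccumulationCurve(
        t=np.arange(1, n + 1), s_mean=s_mean, iterations=iterations, seed=seed
    )


def michaelis_menten(curve: AccumulationCurve) -> RichnessEstimate:
    """Asymptotic richness from S(t) = S_max t / (B + t), Eadie-Hofstee form.

    The hyperbola linearizes as S(t) = S_max - B * (S(t) / t); ordinary least
    squares of s_mean on s_mean/t over t = 1..n gives S_max as the intercept.
    """
    t = np.asarray(curve.t, dtype=float)
    s = np.asarray(curve.s_mean, dtype=float)
    if len(t) < 3:
        raise EstimationError("Michaelis-Menten fit needs >= 3 curve points")
    v = s / t
    if np.ptp(v) < 1e-12 or np.ptp(s) < 1e-12:
        raise EstimationError("degenerate accumulation curve (constant slope)")
    slope, intercept = np.polyfit(v, s, 1)
    return RichnessEstimate(Estimator.MICHAELIS_MENTEN, float(intercept))


def completeness(s_obs: int, est: RichnessEstimate | float) -> float:
    """Sampling completeness 100 * s_obs / s_hat, rounded to 2 decimals."""
    s_hat = est.s_hat if isinstance(est, RichnessEstimate) else float(est)
    if s_hat <= 0:
        raise ValueError("estimated richness must be positive")
    return round(100.0 * s_obs / s_hat, 2)


def estimate_all(
    inc: np.ndarray, iterations: int = 10_000, seed: int = 0
) -> dict[Estimator, RichnessEstimate]:
    """All four estimators plus completeness, from one incidence matrix."""
    counts = frequency_counts(inc)
    curve = accumulation_curve(inc, iterations=iterations, seed=seed)
    out = {}
    for est in (chao1(counts), jackknife1(counts), jackknife2(counts),
                michaelis_menten(curve)):
        out[est.estimator] = RichnessEstimate(
            est.estimator, est.s_hat, completeness(counts.s_obs, est)
        )
    return out
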