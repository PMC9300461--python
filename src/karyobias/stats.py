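"""Exact statistical primitives shared by every analysis stage.

The segregation-error analyses rest on a small set of classical tests:
an exact two-sided binomial test of each chromosome's event count against
the uniform null, a Bonferroni familywise correction over the chromosome
set, Fisher's exact test for 2x2 categorical comparisons, Pearson
correlation for landscape-vs-landscape and landscape-vs-position
comparisons, and a paired ratio t-test for within-nucleus probe distances.

The two-sided binomial test uses the minimum-likelihood convention: the
p-value is the sum of P(i) over all outcomes i whose point probability is
at or below that of the observed count (with a small relative tolerance
when comparing floating-point point probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "NullModel",
    "binomial_two_sided",
    "bonferroni_threshold",
    "is_significant",
    "fisher_two_sided",
    "pearson_r_p",
    "ratio_t_test",
]

# Relative tolerance for point-probability ties in the minimum-likelihood
# two-sided binomial test.
_MINLIKE_RELTOL = 1e-12

# Smallest positive double, returned instead of an exact 0 p-value.
_TINY = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class NullModel:
    """Uniform-error null for per-chromosome mis-segregation.

    With ``n_types`` distinguishable chromosome types (23 for a 46,XX
    diploid karyotype, where the two homologues of each autosome and the
    two X chromosomes are indistinguishable), a random error lands on any
    given type with probability ``p0 = 1/n_types`` — the 4.34% reference
    line.  Bonferroni correction over the same ``n_types`` tests controls
    the familywise error rate at ``alpha``.
    """

    n_types: int = 23
    alpha: float = 0.05
    p0: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError(f"n_types must be >= 1, got {self.n_types}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        object.__setattr__(self, "p0", 1.0 / self.n_types)

    @property
    def null_percent(self) -> float:
        """Expected random per-chromosome error share, in percent."""
        return 100.0 / self.n_types

    @property
    def threshold(self) -> float:
        """Bonferroni-corrected per-test significance threshold."""
        return bonferroni_threshold(self.alpha, self.n_types)


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood convention.

    Sums P(X = i) over every outcome i in 0..n with
    P(X = i) <= P(X = k) * (1 + 1e-12), for X ~ Binomial(n, p0).

    Parameters
    ----------
    k : observed successes, 0 <= k <= n
    n : number of trials
    p0 : null success probability

    Returns
    -------
    p-value in [0, 1].
    """
    k = int(k)
    n = int(n)
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if p0 in (0.0, 1.0):
        # Degenerate distribution: all mass on 0 or n.
        expected = n if p0 == 1.0 else 0
        return 1.0 if k == expected else 0.0
    i = np.arange(n + 1)
    pmf = sps.binom.pmf(i, n, p0)
    p_obs = pmf[k]
    p = float(pmf[pmf <= p_obs * (1.0 + _MINLIKE_RELTOL)].sum())
    return min(p, 1.0)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling familywise error at alpha."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def is_significant(p_value: float, alpha: float, m: int) -> bool:
    """Bonferroni significance: p < alpha/m."""
    return p_value < bonferroni_threshold(alpha, m)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed that of the observed table.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    if sum(counts) == 0:
        raise ValueError("all-zero 2x2 table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient with two-sided p-value.

    The p-value comes from the t-transform r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.  Perfectly collinear input (|r| = 1) yields the
    smallest positive double rather than an exact zero p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p) if p > 0 else _TINY


def ratio_t_test(pairs) -> tuple[float, float]:
    """Paired ratio t-test: one-sample t-test of log(d1/d2) against 0.

    Used for within-nucleus comparisons of two probe distances (e.g. the
    radial distances of two FISH probes in the same nucleus).  Both
    distances must be strictly positive; the base of the logarithm does
    not affect the statistic.

    Returns
    -------
    (t, p) : test statistic and two-sided p-value.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of distances")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs for a t-test")
    if np.any(arr <= 0):
        raise ValueError("distances must be strictly positive")
    log_ratio = np.log(arr[:, 0]) - np.log(arr[:, 1])
    if np.ptp(log_ratio) == 0:
        # Zero sample variance: t is 0 when the common ratio is 1, else
        # the deviation is infinitely many standard errors from zero.
        if log_ratio[0] == 0:
            return 0.0, 1.0
        return float(np.sign(log_ratio[0]) * np.inf), _TINY
    t, p = sps.ttest_1samp(log_ratio, 0.0)
    return float(t), float(p)
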