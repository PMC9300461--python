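"""Aneuploidy landscapes: per-chromosome error shares vs a uniform null.

The headline statistic: pool every called segregation-error event over a
cohort, compute each chromosome's share of the total (in percent), and
test each chromosome's event count against Binomial(N, 1/23) with a
two-sided exact test, Bonferroni-corrected over the 23 chromosome types.
The uniform-null reference line is 100/23 = 4.3478...% and the corrected
significance threshold is 0.05/23 ~ 0.0022.

Gains and losses are pooled for the test (the null concerns *which*
chromosome errs, not the direction); the four category counts (lost,
gained, partially lost, partially gained) are retained for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import NullModel, binomial_two_sided, is_significant, pearson_r_p

__all__ = [
    "Landscape",
    "build_landscape",
    "compare_landscapes",
    "fish_error_frequency",
]

_CATEGORIES = ("lost", "gained", "partially_lost", "partially_gained")


def _category(extent: str, direction: str) -> str:
    word = "lost" if direction == "loss" else "gained"
    return word if extent == "whole" else f"partially_{word}"


@dataclass
class Landscape:
    """Per-chromosome event counts, shares and test results."""

    table: pd.DataFrame  # indexed by chromosome
    n_events: int
    null: NullModel

    @property
    def shares(self) -> pd.Series:
        return self.table["share_percent"]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def build_landscape(events, null: NullModel, chromosomes: list[str]) -> Landscape:
    """Aggregate events into a tested per-chromosome landscape.

    ``events`` is any iterable of objects with ``chrom``, ``extent`` and
    ``direction`` attributes (simulated truth events or caller output).
    Each event contributes once; the share denominator is the total
    event count N.  Each chromosome's count is tested against
    Binomial(N, p0) two-sided, with Bonferroni over ``null.n_types``.
    """
    events = list(events)
    n = len(events)
    if n == 0:
        raise ValueError("cannot build a landscape from zero events")
    counts = {c: dict.fromkeys(_CATEGORIES, 0) for c in chromosomes}
    for e in events:
        if e.chrom not in counts:
            raise ValueError(f"event on unknown chromosome {e.chrom!r}")
        counts[e.chrom][_category(e.extent, e.direction)] += 1
    rows = []
    for chrom in chromosomes:
        k = sum(counts[chrom].values())
        p = binomial_two_sided(k, n, null.p0)
        rows.append(
            {
                "chrom": chrom,
                **counts[chrom],
                "n_events": k,
                "share_percent": 100.0 * k / n,
                "p_value": p,
                "significant": is_significant(p, null.alpha, null.n_types),
            }
        )
    table = pd.DataFrame(rows).set_index("chrom")
    return Landscape(table=table, n_events=n, null=null)


def compare_landscapes(
    a: Landscape, b: Landscape, exclude: tuple[str, ...] = ()
) -> tuple[float, float]:
    """Pearson r and p between two landscapes' per-chromosome shares.

    Chromosome sets must match after removing the explicit exclusion
    list (e.g. a chromosome that was heterogeneously aneuploid in the
    control condition and therefore not quantified).
    """
    ia = [c for c in a.table.index if c not in exclude]
    ib = [c for c in b.table.index if c not in exclude]
    if ia != ib:
        raise ValueError("chromosome sets differ; pass an explicit exclusion list")
    return pearson_r_p(
        a.table.loc[ia, "share_percent"].to_numpy(),
        b.table.loc[ib, "share_percent"].to_numpy(),
    )


def fish_error_frequency(
    positive: int, total: int, confidence: float = 0.95
) -> dict:
    """Mis-segregation share of a FISH-probed chromosome, in percent.

    The estimate is 100 * positive / total where ``positive`` counts
    mis-segregating probe-positive chromosomes and ``total`` all
    mis-segregating chromosomes, with an exact Clopper-Pearson interval.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= positive <= total:
        raise ValueError("need 0 <= positive <= total")
    alpha = 1.0 - confidence
    lo = (
        0.0 if positive == 0
        else float(sps.beta.ppf(alpha / 2, positive, total - positive + 1))
    )
    hi = (
        1.0 if positive == total
        else float(sps.beta.ppf(1 - alpha / 2, positive + 1, total - positive))
    )
    return {
        "percent": 100.0 * positive / total,
        "ci_low_percent": 100.0 * lo,
        "ci_high_percent": 100.0 * hi,
        "n": total,
    }
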