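"""Micronucleus content: presence calls, bulk shares and enrichment.

Micronuclei form around mis-segregated chromosomes; sequencing sorted
micronuclei reveals which chromosomes they contain.  Two read-outs:

* single-micronucleus mode — each sorted micronucleus yields a sparse
  read set; a chromosome is called *present* when enough of its bins are
  covered, giving a per-chromosome entrapment fraction over the cohort;
* bulk mode — reads from a pooled micronucleus sort are summed per
  chromosome, normalized by the chromosome's bin count and rescaled to
  percent, optionally corrected for constitutive segmental trisomies
  (e.g. a q-arm present in three copies) using a matched bulk-nuclei
  profile, and expressed as log2 enrichment over the primary-nuclei
  profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "MicronucleusSample",
    "mn_presence",
    "presence_matrix",
    "bulk_chrom_percent",
    "correct_trisomic_segment",
    "log2_enrichment",
]

log = logging.getLogger(__name__)

MIN_READS_SINGLE_MN = 50


@dataclass
class MicronucleusSample:
    """Read counts over the bin grid for one sorted (micro)nucleus pool."""

    sample_id: str
    mode: str  # "single" | "bulk"
    counts: np.ndarray  # per-bin, genome-wide

    def __post_init__(self) -> None:
        if self.mode not in ("single", "bulk"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("negative read counts")


def mn_presence(
    sample: MicronucleusSample,
    genome: GenomeSpec,
    min_frac: float = 0.1,
) -> dict[str, tuple[int, int]] | None:
    """Chromosomes present in one single micronucleus.

    A chromosome is present iff the fraction of its bins with >= 1 read
    is at least ``min_frac``.  Returns, per present chromosome, the
    half-open local bin range actually covered (so partial-chromosome
    content is visible).  Samples with fewer than 50 total reads are
    flagged empty (returns None) and should be excluded from cohort
    fractions.
    """
    if sample.mode != "single":
        raise ValueError("presence calls are defined for single-MN samples")
    counts = np.asarray(sample.counts)
    if counts.sum() < MIN_READS_SINGLE_MN:
        log.info("MN %s below %d reads; flagged empty",
                 sample.sample_id, MIN_READS_SINGLE_MN)
        return None
    present: dict[str, tuple[int, int]] = {}
    for name, sl in genome.chrom_slices().items():
        covered = counts[sl] > 0
        if covered.mean() >= min_frac:
            idx = np.flatnonzero(covered)
            present[name] = (int(idx[0]), int(idx[-1] + 1))
    return present


def presence_matrix(
    samples: list[MicronucleusSample],
    genome: GenomeSpec,
    min_frac: float = 0.1,
) -> tuple[pd.DataFrame, int]:
    """0/1 MN x chromosome presence matrix over a single-MN cohort.

    Returns the matrix and the number of empty samples excluded.
    """
    rows = {}
    n_empty = 0
    for s in samples:
        present = mn_presence(s, genome, min_frac=min_frac)
        if present is None:
            n_empty += 1
            continue
        rows[s.sample_id] = {
            name: int(name in present) for name in genome.names
        }
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=genome.names)
    return mat, n_empty


def bulk_chrom_percent(
    counts: np.ndarray, genome: GenomeSpec
) -> pd.Series:
    """Bin-count-normalized per-chromosome read percentages.

    All reads mapped to a chromosome are summed and divided by that
    chromosome's bin count; the per-bin rates are then rescaled to sum
    to 100%.  Under uniform coverage every chromosome gets exactly
    100/23 %.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("zero total reads")
    rates = {
        name: counts[sl].sum() / (sl.stop - sl.start)
        for name, sl in genome.chrom_slices().items()
    }
    s = pd.Series(rates, name="percent")
    return 100.0 * s / s.sum()


def correct_trisomic_segment(
    mn_percent: pd.Series,
    nuclei_percent: pd.Series,
    chromosomes: list[str],
    n_types: int | None = None,
) -> pd.Series:
    """Correct MN shares for constitutive copy-number deviations.

    For each listed chromosome the MN share is divided by the matched
    primary-nuclei observed/expected ratio (observed = that chromosome's
    bulk-nuclei share, expected = the uniform 100/n share), removing the
    inflation a constitutive segmental trisomy causes in both profiles;
    the corrected chromosomes are held fixed and the remaining shares are
    rescaled so the total is again 100%.  With an exactly diploid nuclei
    profile the correction is the identity.
    """
    if not mn_percent.index.equals(nuclei_percent.index):
        raise ValueError("MN and nuclei profiles must share a chromosome set")
    n = n_types if n_types is not None else len(mn_percent)
    expected = 100.0 / n
    corrected = mn_percent.astype(float).copy()
    for chrom in chromosomes:
        ratio = nuclei_percent[chrom] / expected
        if ratio <= 0:
            raise ValueError(f"non-positive nuclei share for {chrom}")
        corrected[chrom] = corrected[chrom] / ratio
    fixed = corrected.index.isin(chromosomes)
    rest_target = 100.0 - corrected[fixed].sum()
    rest_sum = corrected[~fixed].sum()
    if rest_sum > 0:
        corrected[~fixed] *= rest_target / rest_sum
    return corrected


def log2_enrichment(
    mn_percent: pd.Series, nuclei_percent: pd.Series
) -> pd.Series:
    """Per-chromosome log2(MN share / nuclei share)."""
    if not mn_percent.index.equals(nuclei_percent.index):
        raise ValueError("profiles must share a chromosome set")
    if (nuclei_percent <= 0).any():
        raise ValueError("nuclei shares must be strictly positive")
    with np.errstate(divide="ignore"):
        # a chromosome never seen in micronuclei maps to -inf
        return np.log2(mn_percent / nuclei_percent).rename("log2_enrichment")
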