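"""Genome model: chromosome set, bin grid and baseline karyotype.

The analyses treat the genome as 23 distinguishable chromosome types
(autosomes 1-22 plus X in a 46,XX karyotype; the two homologues of a type
are indistinguishable in binned copy-number data).  Each chromosome
carries the attributes the position-dependent error model needs: its bin
count on the analysis grid, its centromere position (splitting p and q
arms), its baseline copy number, its mean relative radial position in the
interphase nucleus, and the true fraction of its bins that are
lamina-associated.

Radial position and LAD fraction both increase with chromosome size —
large chromosomes sit near the nuclear periphery, while the acrocentrics
that organize nucleoli (14, 15, 21, 22) sit centrally — and these two
attributes are what the simulator's mis-segregation bias is driven by.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChromosomeSpec", "GenomeSpec", "human_genome"]

# Approximate chromosome lengths and centromere positions (Mb), hg38.
_CHROM_MB = {
    "1": (249, 123), "2": (243, 93), "3": (198, 91), "4": (190, 50),
    "5": (182, 48), "6": (171, 60), "7": (159, 60), "8": (145, 45),
    "9": (138, 43), "10": (134, 40), "11": (135, 53), "12": (133, 35),
    "13": (114, 17), "14": (107, 17), "15": (102, 19), "16": (90, 37),
    "17": (83, 25), "18": (80, 17), "19": (59, 26), "20": (64, 28),
    "21": (47, 12), "22": (51, 15), "X": (156, 61),
}
_ACROCENTRIC_CENTRAL = {"14", "15", "21", "22"}


@dataclass(frozen=True)
class ChromosomeSpec:
    """One distinguishable chromosome type on the analysis bin grid."""

    name: str
    n_bins: int
    centromere_bin: int
    baseline_copies: int = 2
    radial_mean: float = 0.5
    lad_fraction_true: float = 0.3

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"{self.name}: n_bins must be >= 2")
        if not 0 < self.centromere_bin < self.n_bins:
            raise ValueError(f"{self.name}: centromere_bin out of range")
        if not 0.0 <= self.radial_mean <= 1.0:
            raise ValueError(f"{self.name}: radial_mean outside [0, 1]")
        if not 0.0 <= self.lad_fraction_true <= 1.0:
            raise ValueError(f"{self.name}: lad_fraction_true outside [0, 1]")
        if self.baseline_copies < 0:
            raise ValueError(f"{self.name}: negative baseline_copies")


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome set with a shared bin grid.

    ``bin_size`` is the bin width in base pairs (used only when writing
    BED coordinates).  ``segment_overrides`` lists constitutive segmental
    copy-number deviations from each chromosome's baseline, as
    ``(chrom, start_bin, end_bin, copies)`` with bin indices local to the
    chromosome and half-open — e.g. the q-arm of chromosome 10 present in
    three copies in RPE1-hTERT cells.
    """

    chromosomes: tuple[ChromosomeSpec, ...]
    bin_size: int = 1_000_000
    segment_overrides: tuple[tuple[str, int, int, int], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for chrom, lo, hi, copies in self.segment_overrides:
            spec = self[chrom]
            if not (0 <= lo < hi <= spec.n_bins) or copies < 0:
                raise ValueError(f"bad segment override on {chrom}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_types(self) -> int:
        return len(self.chromosomes)

    @property
    def n_bins(self) -> int:
        return int(sum(c.n_bins for c in self.chromosomes))

    def __getitem__(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def chrom_slices(self) -> dict[str, slice]:
        """Global bin-index slice of each chromosome, in genome order."""
        out: dict[str, slice] = {}
        start = 0
        for c in self.chromosomes:
            out[c.name] = slice(start, start + c.n_bins)
            start += c.n_bins
        return out

    def bin_table(self) -> pd.DataFrame:
        """The bin grid as a BED-like table (0-based half-open)."""
        rows = []
        for c in self.chromosomes:
            starts = np.arange(c.n_bins, dtype=np.int64) * self.bin_size
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c.name,
                        "start": starts,
                        "end": starts + self.bin_size,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def baseline_profile(self) -> np.ndarray:
        """Per-bin baseline integer copy numbers, overrides applied."""
        profile = np.concatenate(
            [np.full(c.n_bins, c.baseline_copies, dtype=np.int64)
             for c in self.chromosomes]
        )
        slices = self.chrom_slices()
        for chrom, lo, hi, copies in self.segment_overrides:
            sl = slices[chrom]
            profile[sl.start + lo : sl.start + hi] = copies
        return profile

    def radial_means(self) -> np.ndarray:
        return np.array([c.radial_mean for c in self.chromosomes])

    def lad_fractions(self) -> np.ndarray:
        return np.array([c.lad_fraction_true for c in self.chromosomes])


def human_genome(
    bin_size: int = 1_000_000,
    scale: float = 1.0,
    rpe1_10q_trisomy: bool = False,
) -> GenomeSpec:
    """The 23-type 46,XX genome on a 1-Mb-style analysis grid.

    ``scale`` shrinks every chromosome's bin count proportionally (a
    scale-0.2 genome has ~600 bins genome-wide instead of ~3,000), which
    keeps simulation demos fast while preserving relative chromosome
    sizes, arm ratios and the radial/LAD structure.

    Radial position grows linearly with chromosome size, with the
    nucleolus-associated acrocentrics (14, 15, 21, 22) pulled toward the
    centre; the true LAD fraction tracks radial position.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    lengths = {k: v[0] for k, v in _CHROM_MB.items()}
    lo, hi = min(lengths.values()), max(lengths.values())
    chroms = []
    for name, (length_mb, cen_mb) in _CHROM_MB.items():
        n_bins = max(4, int(round(length_mb * scale)))
        cen = min(max(1, int(round(cen_mb * scale))), n_bins - 1)
        size_norm = (length_mb - lo) / (hi - lo)
        radial = 0.30 + 0.50 * size_norm
        if name in _ACROCENTRIC_CENTRAL:
            radial -= 0.18
        radial = float(np.clip(radial, 0.05, 0.95))
        lad = float(np.clip(0.10 + 0.55 * radial, 0.0, 0.9))
        chroms.append(
            ChromosomeSpec(
                name=name,
                n_bins=n_bins,
                centromere_bin=cen,
                baseline_copies=2,
                radial_mean=radial,
                lad_fraction_true=lad,
            )
        )
    overrides: tuple[tuple[str, int, int, int], ...] = ()
    if rpe1_10q_trisomy:
        chr10 = next(c for c in chroms if c.name == "10")
        overrides = (("10", chr10.centromere_bin, chr10.n_bins, 3),)
    return GenomeSpec(
        chromosomes=tuple(chroms),
        bin_size=bin_size,
        segment_overrides=overrides,
    )
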