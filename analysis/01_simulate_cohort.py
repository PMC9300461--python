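#!/usr/bin/env python
"""Simulate the study cohort: one error-prone mitosis per cell.

Generates 200 daughter nuclei on the scaled 23-chromosome grid with the
position-dependent error model (beta = 3, ~5.5 events per aneuploid
cell, 80% of cells aneuploid), renders negative-binomial read counts,
entraps mis-segregated chromosomes in micronuclei (p = 0.3), and emits
the DamID-style lamina track.  Writes the bin grid, count matrix, truth
ledger and lamina track under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from karyobias.genome import human_genome
from karyobias.io import write_bed, write_counts
from karyobias.simulate import ErrorModel, SequencingModel, make_lam_track, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = human_genome(scale=0.2)
    rng = np.random.default_rng(SEED)
    cohort = simulate_cohort(
        genome, ErrorModel(), SequencingModel(reads_per_cell=160_000),
        n_cells=200, rng=rng,
    )
    write_bed(genome.bin_table(), OUT / "bins.bed")
    write_counts(cohort.counts, OUT / "counts.tsv")
    cohort.truth.event_table().to_csv(OUT / "truth_events.csv", index=False)
    if cohort.micronuclei:
        import pandas as pd

        pd.DataFrame(cohort.micronuclei).to_csv(OUT / "mn_counts.tsv", sep="\t")
    track = make_lam_track(genome, np.random.default_rng(SEED + 1))
    track.to_csv(OUT / "lam_track.tsv", sep="\t", index=False)
    n_events = len(cohort.truth.events)
    n_aneu = sum(1 for c in cohort.truth.cells if c.events)
    print(
        f"simulated 200 cells ({n_aneu} aneuploid), {n_events} true events "
        f"({n_events / max(n_aneu, 1):.2f} per aneuploid cell), "
        f"{len(cohort.micronuclei)} micronuclei -> {OUT}"
    )


if __name__ == "__main__":
    main()
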