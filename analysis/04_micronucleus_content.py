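#!/usr/bin/env python
"""Quantify micronucleus chromosomal content.

Reads the single-micronucleus count table from 01, calls per-MN
chromosome presence, pools reads into bin-normalized per-chromosome
percentages, and computes log2 enrichment over the cohort's bulk-nuclei
profile.  The enrichment vector is compared with the aneuploidy
landscape from 03 — chromosomes that mis-segregate often should also
dominate micronuclei.  Writes tables under results/mn/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from karyobias.genome import human_genome
from karyobias.io import read_counts
from karyobias.mn import MicronucleusSample, bulk_chrom_percent, log2_enrichment, presence_matrix
from karyobias.stats import pearson_r_p

IN = Path("results/cohort")
OUT = Path("results/mn")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = human_genome(scale=0.2)
    mn_counts = pd.read_csv(IN / "mn_counts.tsv", sep="\t", index_col=0)
    samples = [
        MicronucleusSample(str(idx), "single", row.to_numpy())
        for idx, row in mn_counts.iterrows()
    ]
    mat, n_empty = presence_matrix(samples, genome)
    mat.to_csv(OUT / "presence.tsv", sep="\t")

    pooled = mn_counts.to_numpy().sum(axis=0)
    mn_pct = bulk_chrom_percent(pooled, genome)
    nuclei = read_counts(IN / "counts.tsv").to_numpy().sum(axis=0)
    nuclei_pct = bulk_chrom_percent(nuclei, genome)
    enrich = log2_enrichment(mn_pct, nuclei_pct)
    pd.DataFrame(
        {"mn_percent": mn_pct, "nuclei_percent": nuclei_pct,
         "log2_enrichment": enrich}
    ).to_csv(OUT / "content.csv")

    scape = pd.read_csv("results/landscape/landscape.csv",
                        dtype={"chrom": str}).set_index("chrom")
    finite = np.isfinite(enrich.reindex(genome.names))
    r, p = pearson_r_p(
        enrich.reindex(genome.names)[finite].to_numpy(),
        scape["share_percent"].reindex(genome.names)[finite].to_numpy(),
    )
    (OUT / "report.json").write_text(json.dumps(
        {"n_mn": len(mat), "n_empty_excluded": n_empty,
         "enrichment_vs_landscape_r": r, "p": p}, indent=2,
    ))
    print(
        f"{len(mat)} micronuclei ({n_empty} empty excluded); "
        f"log2 enrichment vs landscape shares: r={r:.3f}, p={p:.2g}"
    )


if __name__ == "__main__":
    main()
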