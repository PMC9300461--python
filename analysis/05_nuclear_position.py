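#!/usr/bin/env python
"""Correlate error shares with nuclear-position measures.

Calls lamina-associated domains from the DamID-style track of 01,
computes each chromosome's LAD percentage, and correlates it with the
aneuploidy landscape from 03.  Peripheral (LAD-rich) chromosomes are
expected to carry more segregation errors.  Writes results/position/.
"""

import json
from pathlib import Path

import pandas as pd

from karyobias.position import lad_call, lad_percent, position_error_correlation

IN = Path("results/cohort")
OUT = Path("results/position")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    track = pd.read_csv(IN / "lam_track.tsv", sep="\t", dtype={"chrom": str})
    labels = lad_call(track)
    pct = lad_percent(track, labels)
    pct.to_csv(OUT / "lad_percent.csv")
    scape = pd.read_csv("results/landscape/landscape.csv",
                        dtype={"chrom": str}).set_index("chrom")
    r, p = position_error_correlation(scape["share_percent"], pct)
    (OUT / "report.json").write_text(
        json.dumps({"lad_vs_share_r": r, "p": p}, indent=2)
    )
    print(f"LAD% vs error share over 23 chromosomes: r={r:.3f}, p={p:.2g}")


if __name__ == "__main__":
    main()
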