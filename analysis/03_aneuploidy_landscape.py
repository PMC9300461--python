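#!/usr/bin/env python
"""Build the aneuploidy landscape and test it against the uniform null.

Pools the called events from 02 into per-chromosome error shares, tests
each chromosome against Binomial(N, 1/23) with Bonferroni correction,
and reports which chromosomes err more (or less) often than the 4.3%
random expectation.  Writes the landscape table under results/landscape/.
"""

import json
from pathlib import Path

import pandas as pd

from karyobias.genome import human_genome
from karyobias.landscape import build_landscape
from karyobias.stats import NullModel

IN = Path("results/calls")
OUT = Path("results/landscape")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = human_genome(scale=0.2)
    events = pd.read_csv(IN / "events.csv", dtype={"chrom": str})
    null = NullModel()
    scape = build_landscape(
        list(events.itertuples(index=False)), null, genome.names
    )
    scape.table.to_csv(OUT / "landscape.csv")
    sig = scape.significant()
    report = {
        "n_events": scape.n_events,
        "null_percent": null.null_percent,
        "bonferroni_threshold": null.threshold,
        "significant_high": sorted(
            sig[sig["share_percent"] > null.null_percent].index.tolist()
        ),
        "significant_low": sorted(
            sig[sig["share_percent"] < null.null_percent].index.tolist()
        ),
    }
    (OUT / "report.json").write_text(json.dumps(report, indent=2))
    print(
        f"N={scape.n_events} events; null line {null.null_percent:.2f}%; "
        f"threshold {null.threshold:.4f}; "
        f"high: {report['significant_high']}; low: {report['significant_low']}"
    )


if __name__ == "__main__":
    main()
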