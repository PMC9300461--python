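"""End-to-end pipeline: simulate -> call -> landscape -> MN -> position -> geometry.

Each stage reads the previous stage's in-memory objects, writes its
tables under the run's output directory, and the run closes with a
manifest of config hash, seed and per-file checksums.  Stage RNGs are
derived deterministically from the single run seed, so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, geometry, landscape, mn, position, simulate
from .io import RunConfig, write_bed, write_counts, write_manifest
from .stats import NullModel

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _events_to_frame(events_by_cell: dict) -> pd.DataFrame:
    rows = [
        {
            "cell_id": e.cell_id, "chrom": e.chrom, "extent": e.extent,
            "arm": e.arm, "direction": e.direction,
            "start_bin": e.start_bin, "end_bin": e.end_bin,
            "copies_from": e.copies_from, "copies_to": e.copies_to,
        }
        for evs in events_by_cell.values()
        for e in evs
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "chrom", "extent", "arm", "direction",
                 "start_bin", "end_bin", "copies_from", "copies_to"],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated cohort; returns the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = config.genome()
    outputs: list[str] = []
    results: dict = {"genome_bins": genome.n_bins}

    stage = "simulate"
    try:
        cohort = simulate.simulate_cohort(
            genome, config.error_model, config.sequencing,
            config.n_cells, config.child_rng("cohort"),
        )
        lam = simulate.make_lam_track(genome, config.child_rng("lam"))
        battery = simulate.make_geometry_battery(
            config.child_rng("geometry"), n_points=config.n_geometry_points
        )
        outcomes = simulate.make_outcome_battery(
            config.child_rng("outcomes"), n_cells=config.n_outcome_cells
        )
        write_bed(genome.bin_table(), out / "bins.bed")
        write_counts(cohort.counts, out / "counts.tsv")
        cohort.truth.event_table().to_csv(out / "truth_events.csv", index=False)
        lam.drop(columns="is_lad_true").to_csv(
            out / "lam_track.tsv", sep="\t", index=False
        )
        outputs += ["bins.bed", "counts.tsv", "truth_events.csv", "lam_track.tsv"]

        stage = "call"
        profiles, called = cnv.call_cohort(cohort.counts, genome, config.hmm)
        flags, call_summary = cnv.classify_cells(called)
        _events_to_frame(called).to_csv(out / "events.csv", index=False)
        flags.to_csv(out / "cell_flags.csv", index=False)
        outputs += ["events.csv", "cell_flags.csv"]
        results["call_summary"] = call_summary

        stage = "landscape"
        null = NullModel(n_types=genome.n_types)
        called_events = [e for evs in called.values() for e in evs]
        scape = landscape.build_landscape(called_events, null, genome.names)
        scape.table.to_csv(out / "landscape.csv")
        outputs.append("landscape.csv")
        results["landscape"] = {
            "n_events": scape.n_events,
            "null_percent": null.null_percent,
            "bonferroni_threshold": null.threshold,
            "n_significant": int(scape.table["significant"].sum()),
        }

        stage = "mn"
        samples = [
            mn.MicronucleusSample(str(s.name), "single", s.to_numpy())
            for s in cohort.micronuclei
        ]
        results["mn"] = {"n_micronuclei": len(samples)}
        if samples:
            mat, n_empty = mn.presence_matrix(samples, genome)
            mat.to_csv(out / "mn_presence.tsv", sep="\t")
            outputs.append("mn_presence.tsv")
            pooled = np.sum([s.counts for s in samples], axis=0)
            mn_pct = mn.bulk_chrom_percent(pooled, genome)
            nuclei_pct = mn.bulk_chrom_percent(
                cohort.counts.to_numpy().sum(axis=0), genome
            )
            enrich = mn.log2_enrichment(mn_pct, nuclei_pct)
            pd.DataFrame(
                {"mn_percent": mn_pct, "nuclei_percent": nuclei_pct,
                 "log2_enrichment": enrich}
            ).to_csv(out / "mn_content.csv")
            outputs.append("mn_content.csv")
            results["mn"]["n_empty_excluded"] = n_empty

        stage = "position"
        labels = position.lad_call(lam)
        lad_pct = position.lad_percent(lam, labels)
        lad_pct.to_csv(out / "lad_percent.csv")
        outputs.append("lad_percent.csv")
        r, p = position.position_error_correlation(scape.shares, lad_pct)
        results["position"] = {"lad_share_pearson_r": r, "lad_share_pearson_p": p}

        stage = "geometry"
        pts = battery["points"]
        pred = [
            geometry.position_category(
                (row.x_um, row.y_um), battery["vertices"],
                battery["poles"][0], battery["poles"][1], config.geometry,
            )
            for row in pts.itertuples()
        ]
        pts = pts.assign(predicted=pred)
        pts.to_csv(out / "geometry_classes.csv", index=False)
        outputs.append("geometry_classes.csv")
        results["geometry"] = {
            "shell_polar_accuracy": float(
                (pts["predicted"] == pts["true_class"]).mean()
            ),
        }
        outcome_pred = [
            geometry.classify_outcome(c["kinetochores"], c["poles"], config.geometry)
            for c in outcomes
        ]
        results["geometry"]["outcome_accuracy"] = float(
            np.mean([p == c["true_label"] for p, c in zip(outcome_pred, outcomes)])
        )
    except Exception:
        log.error("pipeline failed in stage %r; partial outputs kept in %s",
                  stage, out)
        raise

    (out / "results.json").write_text(json.dumps(results, indent=2))
    outputs.append("results.json")
    write_manifest(out, config, outputs)
    return results
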