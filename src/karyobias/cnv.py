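"""Single-cell copy-number calling and segregation-event extraction.

Binned read counts from one nucleus are normalized to copy units,
segmented per chromosome by a negative-binomial-emission hidden Markov
model (Viterbi decoding over integer copy states), and deviations from
the baseline karyotype are extracted as whole- or arm-level
segregation-error events.  This codifies what is done manually on top of
HMM segmentation in single-cell karyotype sequencing: an event is
"whole" when it spans (almost) the entire chromosome, short blips are
discarded as noise, and a cell is aneuploid iff it carries at least one
event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeSpec

__all__ = [
    "HMMParams",
    "EventCall",
    "ZeroCoverageError",
    "normalize_cell",
    "viterbi_profile",
    "extract_events",
    "classify_cells",
    "call_cohort",
    "evaluate_calls",
]

log = logging.getLogger(__name__)


class ZeroCoverageError(ValueError):
    """Raised when a cell has no reads and cannot be normalized."""


@dataclass(frozen=True)
class HMMParams:
    """Segmentation parameters.

    max_copies
        Highest copy state; states are 0..max_copies.
    self_transition
        Per-bin probability of staying in the same state.
    dispersion
        Negative-binomial size parameter of the emissions.
    state0_floor
        Emission mean of the zero-copy state, as a fraction of the
        per-copy depth (avoids zero-likelihood degeneracy).
    f_whole
        Minimum fraction of a chromosome's bins an event must cover to
        be labelled whole rather than partial.
    min_bins
        Deviant runs shorter than this are discarded as noise.
    """

    max_copies: int = 4
    self_transition: float = 0.999
    dispersion: float = 20.0
    state0_floor: float = 0.05
    f_whole: float = 0.9
    min_bins: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.self_transition < 1.0:
            raise ValueError("self_transition must be in (0, 1)")
        if self.max_copies < 1:
            raise ValueError("max_copies must be >= 1")
        if self.dispersion <= 0 or not 0 < self.state0_floor < 1:
            raise ValueError("bad emission parameters")


@dataclass(frozen=True)
class EventCall:
    """One called copy-number event in one cell."""

    cell_id: str
    chrom: str
    extent: str  # "whole" | "partial"
    arm: str  # "p" | "q" | "spanning"
    direction: str  # "gain" | "loss"
    start_bin: int  # local to chromosome, half-open
    end_bin: int
    copies_from: int
    copies_to: int

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("empty bin range")
        if self.copies_from == self.copies_to:
            raise ValueError("copies_from must differ from copies_to")


def normalize_cell(
    counts: np.ndarray, baseline: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scale raw bin counts to copy units.

    The per-copy depth is the median of count/baseline over bins with a
    positive baseline, which maps the genome-wide median bin to its
    baseline copy number even when a minority of bins deviates.

    Returns (rates in copy units, per-copy depth).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ZeroCoverageError("cell has no reads")
    base = np.asarray(baseline, dtype=float)
    mask = base > 0
    depth = float(np.median(counts[mask] / base[mask]))
    if depth <= 0:
        raise ZeroCoverageError("per-copy depth is zero")
    return counts / depth, depth


def _nb_log_emissions(
    counts: np.ndarray, depth: float, params: HMMParams
) -> np.ndarray:
    """(n_states, n_bins) log-likelihood matrix of NB emissions."""
    states = np.arange(params.max_copies + 1, dtype=float)
    mu = depth * np.where(states == 0, params.state0_floor, states)
    size = params.dispersion
    p = size / (size + mu)
    return sps.nbinom.logpmf(
        np.round(counts)[None, :], size, p[:, None]
    )


def viterbi_profile(
    counts: np.ndarray,
    depth: float,
    genome: GenomeSpec,
    params: HMMParams,
) -> np.ndarray:
    """Maximum-a-posteriori integer copy path, per chromosome.

    Chains never cross chromosome boundaries; within a chromosome the
    transition matrix holds ``self_transition`` on the diagonal and
    spreads the remainder uniformly over other states.  The initial
    distribution is uniform.
    """
    counts = np.asarray(counts, dtype=float)
    n_states = params.max_copies + 1
    log_stay = np.log(params.self_transition)
    log_switch = np.log((1.0 - params.self_transition) / (n_states - 1))
    trans = np.full((n_states, n_states), log_switch)
    np.fill_diagonal(trans, log_stay)
    path = np.empty(counts.size, dtype=np.int64)
    for name, sl in genome.chrom_slices().items():
        emis = _nb_log_emissions(counts[sl], depth, params)
        n_bins = emis.shape[1]
        delta = emis[:, 0] - np.log(n_states)
        back = np.zeros((n_bins, n_states), dtype=np.int64)
        for t in range(1, n_bins):
            cand = delta[:, None] + trans  # prev state x next state
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(n_states)] + emis[:, t]
        state = int(np.argmax(delta))
        chrom_path = np.empty(n_bins, dtype=np.int64)
        chrom_path[-1] = state
        for t in range(n_bins - 1, 0, -1):
            state = int(back[t, state])
            chrom_path[t - 1] = state
        path[sl] = chrom_path
    return path


def extract_events(
    profile: np.ndarray,
    baseline: np.ndarray,
    genome: GenomeSpec,
    cell_id: str = "cell",
    params: HMMParams | None = None,
) -> list[EventCall]:
    """Turn a called copy profile into segregation-error events.

    Maximal runs of constant non-zero deviation from the baseline become
    events; runs shorter than ``min_bins`` are discarded as noise.  An
    event is whole if it covers at least ``f_whole`` of the chromosome's
    bins, otherwise partial, with the arm assigned by centromere overlap
    (p if entirely before the centromere bin, q if entirely at/after it,
    spanning otherwise).
    """
    params = params or HMMParams()
    profile = np.asarray(profile)
    baseline = np.asarray(baseline)
    events: list[EventCall] = []
    for spec, (name, sl) in zip(genome.chromosomes, genome.chrom_slices().items()):
        dev = profile[sl].astype(np.int64) - baseline[sl].astype(np.int64)
        n = spec.n_bins
        i = 0
        while i < n:
            if dev[i] == 0:
                i += 1
                continue
            j = i
            while j < n and dev[j] == dev[i]:
                j += 1
            if j - i >= params.min_bins:
                frac = (j - i) / n
                if frac >= params.f_whole:
                    extent, arm = "whole", "spanning"
                else:
                    extent = "partial"
                    if j <= spec.centromere_bin:
                        arm = "p"
                    elif i >= spec.centromere_bin:
                        arm = "q"
                    else:
                        arm = "spanning"
                base_val = int(np.round(np.median(baseline[sl][i:j])))
                events.append(
                    EventCall(
                        cell_id=cell_id,
                        chrom=name,
                        extent=extent,
                        arm=arm,
                        direction="gain" if dev[i] > 0 else "loss",
                        start_bin=i,
                        end_bin=j,
                        copies_from=base_val,
                        copies_to=base_val + int(dev[i]),
                    )
                )
            i = j
    return events


def classify_cells(
    events_by_cell: dict[str, list[EventCall]]
) -> tuple[pd.DataFrame, dict]:
    """Euploid/aneuploid flags and cohort summary.

    A cell is aneuploid iff it carries at least one event.  The summary
    reports cell counts, total events and mean events per aneuploid cell.
    """
    ids = list(events_by_cell)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids")
    n_events = np.array([len(events_by_cell[c]) for c in ids])
    flags = pd.DataFrame(
        {
            "cell_id": ids,
            "n_events": n_events,
            "status": np.where(n_events > 0, "aneuploid", "euploid"),
        }
    )
    n_aneu = int((n_events > 0).sum())
    summary = {
        "n_cells": len(ids),
        "n_aneuploid": n_aneu,
        "n_euploid": len(ids) - n_aneu,
        "n_events": int(n_events.sum()),
        "mean_events_per_aneuploid_cell": (
            float(n_events[n_events > 0].mean()) if n_aneu else float("nan")
        ),
    }
    return flags, summary


def call_cohort(
    counts: pd.DataFrame,
    genome: GenomeSpec,
    params: HMMParams | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, list[EventCall]]]:
    """Call every cell in a cells x bins count matrix.

    Cells with zero coverage are skipped with a logged warning.
    Returns (profiles by cell, events by cell).
    """
    params = params or HMMParams()
    baseline = genome.baseline_profile()
    profiles: dict[str, np.ndarray] = {}
    events: dict[str, list[EventCall]] = {}
    for cell_id, row in counts.iterrows():
        try:
            rates, depth = normalize_cell(row.to_numpy(), baseline)
        except ZeroCoverageError:
            log.warning("cell %s has no reads; skipped", cell_id)
            continue
        profile = viterbi_profile(row.to_numpy(), depth, genome, params)
        profiles[str(cell_id)] = profile
        events[str(cell_id)] = extract_events(
            profile, baseline, genome, cell_id=str(cell_id), params=params
        )
    return profiles, events


def _overlap(a: EventCall, b: EventCall) -> float:
    """Reciprocal overlap of two events on the same chromosome."""
    inter = min(a.end_bin, b.end_bin) - max(a.start_bin, b.start_bin)
    if inter <= 0:
        return 0.0
    return inter / max(a.end_bin - a.start_bin, b.end_bin - b.start_bin)


def evaluate_calls(
    truth_profiles: dict[str, np.ndarray],
    called_events: dict[str, list[EventCall]],
    genome: GenomeSpec,
    params: HMMParams | None = None,
    min_overlap: float = 0.5,
) -> dict:
    """Event-level precision/recall/F1 of calls against truth profiles.

    The reference event set is derived by running the same event
    extraction on the *noiseless* truth profiles, so events below the
    caller's ``min_bins`` detectability floor are excluded from both
    sides and stacked same-direction events are merged consistently.
    A called event matches a reference event when cell, chromosome and
    direction agree and reciprocal bin overlap is >= ``min_overlap``.
    """
    params = params or HMMParams()
    baseline = genome.baseline_profile()
    tp = fp = fn = 0
    for cell_id, truth_profile in truth_profiles.items():
        ref = extract_events(truth_profile, baseline, genome, cell_id, params)
        called = list(called_events.get(cell_id, []))
        used = [False] * len(called)
        for r in ref:
            match = -1
            for i, c in enumerate(called):
                if used[i] or c.chrom != r.chrom or c.direction != r.direction:
                    continue
                if _overlap(r, c) >= min_overlap:
                    match = i
                    break
            if match >= 0:
                used[match] = True
                tp += 1
            else:
                fn += 1
        fp += used.count(False)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall, "f1": f1,
    }
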