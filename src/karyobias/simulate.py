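"""Synthetic cohorts with position-dependent mis-segregation.

The generator emulates the data produced by one error-prone mitosis in a
diploid cell population under partial spindle-assembly-checkpoint
inhibition, with the statistical structure the downstream analyses
assume:

* each cell undergoes at most one aberrant division; with probability
  ``p_error_cell`` it acquires ``k`` segregation-error events, ``k``
  drawn from a zero-truncated Poisson whose mean is calibrated to the
  observed ~5.5 events per aneuploid cell;
* the chromosome hit by each event is drawn with probability
  proportional to ``exp(beta * r_c)``, where ``r_c`` is that cell's
  radial-position draw for chromosome ``c`` — the one-parameter monotone
  link between nuclear periphery and mis-segregation propensity
  (``beta = 0`` recovers the uniform-error null, which also models
  position randomization by monopolar-spindle washout);
* events are whole-chromosome with probability ``p_whole``, otherwise
  arm-anchored partial gains/losses; direction is a fair coin, so one
  emitted daughter (the G1-sorted design) gains what its sister loses;
* binned read counts per daughter nucleus follow a negative binomial
  around depth x copy-number, micronuclei entrap mis-segregated
  chromosomes with probability ``p_mn``, and DamID-style lamina tracks
  and mitotic-geometry fixtures are emitted with exact ground truth.

Every stochastic output is reproducible from a ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "ErrorModel",
    "SequencingModel",
    "SimEvent",
    "CellTruth",
    "CohortTruth",
    "Cohort",
    "calibrate_lambda",
    "simulate_cell_errors",
    "replay_events",
    "render_read_counts",
    "spawn_micronuclei",
    "simulate_cohort",
    "make_lam_track",
    "make_geometry_battery",
    "make_outcome_battery",
]

MEAN_EVENTS_PER_ANEUPLOID_CELL = 5.5


def calibrate_lambda(target_mean: float = MEAN_EVENTS_PER_ANEUPLOID_CELL) -> float:
    """Poisson rate whose zero-truncated mean equals ``target_mean``.

    The zero-truncated Poisson has mean lambda / (1 - exp(-lambda));
    solved by fixed-point iteration (monotone, converges fast).
    """
    if target_mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    lam = target_mean
    for _ in range(100):
        new = target_mean * (1.0 - math.exp(-lam))
        if abs(new - lam) < 1e-13:
            break
        lam = new
    return lam


@dataclass(frozen=True)
class ErrorModel:
    """Parameters of the position-dependent segregation-error process.

    beta
        Log-weight per unit relative radial position; 0 = uniform errors.
    lambda_events
        Rate of the zero-truncated Poisson event count per error cell
        (default calibrated so the realized mean is ~5.5).
    p_error_cell
        Fraction of cells undergoing at least one event.
    p_whole
        Probability an event is whole-chromosome (else arm-level partial).
    p_mn
        Probability a mis-segregated chromosome is entrapped in a
        micronucleus.
    radial_concentration
        Concentration of the per-cell Beta draw of each chromosome's
        radial position around its mean (larger = tighter).
    """

    beta: float = 3.0
    lambda_events: float = field(default_factory=calibrate_lambda)
    p_error_cell: float = 0.8
    p_whole: float = 0.8
    p_mn: float = 0.3
    radial_concentration: float = 8.0

    def __post_init__(self) -> None:
        for name in ("p_error_cell", "p_whole", "p_mn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lambda_events <= 0:
            raise ValueError("lambda_events must be positive")
        if self.radial_concentration <= 0:
            raise ValueError("radial_concentration must be positive")

    def null(self) -> "ErrorModel":
        """The same model with the position effect switched off."""
        return replace(self, beta=0.0)


@dataclass(frozen=True)
class SequencingModel:
    """Counting-noise model for shallow single-cell sequencing.

    Per-bin counts are negative binomial with mean
    ``reads x copies_b / sum(copies)`` and size parameter ``dispersion``
    (larger size = closer to Poisson).
    """

    reads_per_cell: float = 800_000.0
    mn_reads_per_bin: float = 100.0
    dispersion: float = 20.0

    def __post_init__(self) -> None:
        if self.reads_per_cell <= 0 or self.mn_reads_per_bin <= 0:
            raise ValueError("read depths must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class SimEvent:
    """One true segregation-error event in one daughter nucleus.

    ``start_bin``/``end_bin`` are half-open indices local to the
    chromosome; ``delta`` is the signed copy change (+1 gain, -1 loss).
    """

    cell_id: str
    chrom: str
    extent: str  # "whole" | "partial"
    arm: str  # "p" | "q" | "spanning"
    direction: str  # "gain" | "loss"
    start_bin: int
    end_bin: int

    @property
    def delta(self) -> int:
        return 1 if self.direction == "gain" else -1


@dataclass
class CellTruth:
    cell_id: str
    events: list[SimEvent]
    profile: np.ndarray  # per-bin true integer copies, genome-wide
    radial: np.ndarray  # this cell's radial draw per chromosome


@dataclass
class CohortTruth:
    """Ground-truth ledger for a simulated cohort."""

    genome: GenomeSpec
    cells: list[CellTruth]
    mn_event_index: list[tuple[int, int]] = field(default_factory=list)
    # (cell index, event index within cell) for each emitted micronucleus

    @property
    def events(self) -> list[SimEvent]:
        return [e for c in self.cells for e in c.events]

    def event_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": e.cell_id,
                "chrom": e.chrom,
                "extent": e.extent,
                "arm": e.arm,
                "direction": e.direction,
                "start_bin": e.start_bin,
                "end_bin": e.end_bin,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "chrom", "extent", "arm",
                "direction", "start_bin", "end_bin",
            ],
        )


@dataclass
class Cohort:
    """Simulated cohort: counts plus the truth ledger."""

    genome: GenomeSpec
    counts: pd.DataFrame  # cells x bins, integer read counts
    truth: CohortTruth
    micronuclei: list["pd.Series"] = field(default_factory=list)


def _draw_radial(genome: GenomeSpec, model: ErrorModel, rng) -> np.ndarray:
    mu = genome.radial_means()
    kappa = model.radial_concentration
    a = np.clip(mu * kappa, 1e-6, None)
    b = np.clip((1.0 - mu) * kappa, 1e-6, None)
    return rng.beta(a, b)


def _zero_truncated_poisson(lam: float, rng) -> int:
    while True:
        k = int(rng.poisson(lam))
        if k > 0:
            return k


def simulate_cell_errors(
    genome: GenomeSpec,
    model: ErrorModel,
    rng: np.random.Generator,
    cell_id: str = "cell",
) -> CellTruth:
    """Simulate one daughter nucleus through an error-prone mitosis.

    Returns the cell's truth record: its per-chromosome radial draws,
    event list and resulting per-bin copy profile.  A loss that would
    drive any bin below zero copies is flipped to a gain, so profiles
    stay non-negative.
    """
    radial = _draw_radial(genome, model, rng)
    profile = genome.baseline_profile().astype(np.int64)
    events: list[SimEvent] = []
    if rng.random() < model.p_error_cell:
        k = _zero_truncated_poisson(model.lambda_events, rng)
        weights = np.exp(model.beta * radial)
        weights = weights / weights.sum()
        slices = genome.chrom_slices()
        for _ in range(k):
            ci = int(rng.choice(genome.n_types, p=weights))
            spec = genome.chromosomes[ci]
            if rng.random() < model.p_whole:
                extent, arm = "whole", "spanning"
                lo, hi = 0, spec.n_bins
            else:
                extent = "partial"
                arm = "p" if rng.random() < 0.5 else "q"
                cen = spec.centromere_bin
                if arm == "p":
                    # telomere-anchored: [0, b) with b in 1..cen
                    lo, hi = 0, int(rng.integers(1, cen + 1))
                else:
                    # [b, n) with b in cen..n-1
                    lo, hi = int(rng.integers(cen, spec.n_bins)), spec.n_bins
            direction = "gain" if rng.random() < 0.5 else "loss"
            sl = slices[spec.name]
            seg = slice(sl.start + lo, sl.start + hi)
            if direction == "loss" and profile[seg].min() <= 0:
                direction = "gain"
            profile[seg] += 1 if direction == "gain" else -1
            events.append(
                SimEvent(cell_id, spec.name, extent, arm, direction, lo, hi)
            )
    return CellTruth(cell_id=cell_id, events=events, profile=profile, radial=radial)


def replay_events(genome: GenomeSpec, events: list[SimEvent]) -> np.ndarray:
    """Apply an event list to the baseline karyotype, bin by bin.

    Independent reconstruction used to check truth-ledger consistency.
    """
    profile = genome.baseline_profile().astype(np.int64)
    slices = genome.chrom_slices()
    for e in events:
        sl = slices[e.chrom]
        profile[sl.start + e.start_bin : sl.start + e.end_bin] += e.delta
    return profile


def render_read_counts(
    true_profile: np.ndarray,
    seq: SequencingModel,
    rng: np.random.Generator,
    total_reads: float | None = None,
) -> np.ndarray:
    """Binned read counts from a true copy profile.

    Gamma-Poisson (negative binomial) noise: bin b has mean
    ``total_reads * copies_b / sum(copies)`` and size ``seq.dispersion``.
    """
    profile = np.asarray(true_profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        raise ValueError("all-zero copy profile cannot be sequenced")
    reads = seq.reads_per_cell if total_reads is None else total_reads
    mu = reads * profile / total
    shape = seq.dispersion
    lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.size) * mu / shape, 0.0)
    return rng.poisson(lam).astype(np.int64)


def spawn_micronuclei(
    cell: CellTruth,
    genome: GenomeSpec,
    model: ErrorModel,
    seq: SequencingModel,
    rng: np.random.Generator,
) -> list[tuple[int, np.ndarray]]:
    """Micronucleus read sets for one cell's events.

    Each event independently becomes a micronucleus with probability
    ``p_mn``; its reads cover only the event's bin range, with expected
    depth ``mn_reads_per_bin`` per bin — total micronucleus read count
    scales with the entrapped segment's size, as the DNA content does.
    Returns ``(event index, genome-wide count vector)`` pairs.
    """
    out: list[tuple[int, np.ndarray]] = []
    slices = genome.chrom_slices()
    for idx, e in enumerate(cell.events):
        if rng.random() >= model.p_mn:
            continue
        counts = np.zeros(genome.n_bins, dtype=np.int64)
        sl = slices[e.chrom]
        seg = slice(sl.start + e.start_bin, sl.start + e.end_bin)
        n = seg.stop - seg.start
        mu = np.full(n, seq.mn_reads_per_bin)
        shape = seq.dispersion
        lam = rng.gamma(shape, 1.0, size=n) * mu / shape
        counts[seg] = rng.poisson(lam)
        out.append((idx, counts))
    return out


def simulate_cohort(
    genome: GenomeSpec,
    error_model: ErrorModel,
    seq_model: SequencingModel,
    n_cells: int,
    rng: np.random.Generator,
    render_counts: bool = True,
    with_micronuclei: bool = True,
) -> Cohort:
    """Simulate ``n_cells`` daughter nuclei (one aberrant mitosis each).

    Set ``render_counts=False`` to skip sequencing noise when only the
    event-level truth is needed (e.g. landscape null calibration).
    """
    cells: list[CellTruth] = []
    mn_index: list[tuple[int, int]] = []
    mn_samples: list[pd.Series] = []
    count_rows = []
    bin_ids = [
        f"{c.name}:{i}" for c in genome.chromosomes for i in range(c.n_bins)
    ]
    for i in range(n_cells):
        cid = f"cell{i:04d}"
        cell = simulate_cell_errors(genome, error_model, rng, cell_id=cid)
        cells.append(cell)
        if render_counts:
            count_rows.append(render_read_counts(cell.profile, seq_model, rng))
        if with_micronuclei:
            for ev_idx, counts in spawn_micronuclei(
                cell, genome, error_model, seq_model, rng
            ):
                mn_index.append((i, ev_idx))
                mn_samples.append(
                    pd.Series(counts, index=bin_ids, name=f"mn{len(mn_samples):04d}")
                )
    counts = (
        pd.DataFrame(
            np.vstack(count_rows) if count_rows else
            np.empty((0, genome.n_bins), dtype=np.int64),
            index=[c.cell_id for c in cells] if count_rows else [],
            columns=bin_ids,
        )
    )
    truth = CohortTruth(genome=genome, cells=cells, mn_event_index=mn_index)
    return Cohort(genome=genome, counts=counts, truth=truth, micronuclei=mn_samples)


# --------------------------------------------------------------------------
# DamID-style lamina tracks


def make_lam_track(
    genome: GenomeSpec,
    rng: np.random.Generator,
    bins_per_unit: int = 10,
    lad_run_bins: int = 20,
    mu_lad: float = 1.0,
    mu_inter: float = -1.0,
    sigma: float = 0.4,
) -> pd.DataFrame:
    """DamID-style per-bin log2(observed/expected) lamina-contact track.

    Each analysis bin is refined into ``bins_per_unit`` 100-kb-style
    track bins.  A fraction ``lad_fraction_true`` of each chromosome's
    track bins (rounded to the exact count) is laid out as contiguous
    LAD runs of ~``lad_run_bins`` bins, alternating with inter-LAD gaps;
    LAD bins draw log2(OE) from N(mu_lad, sigma), inter-LAD bins from
    N(mu_inter, sigma).

    Returns a table with columns chrom, start, end, log2oe, is_lad_true
    (the last is the ground-truth label, not part of the on-disk track
    format).
    """
    track_bin = 100_000
    frames = []
    for spec in genome.chromosomes:
        n = spec.n_bins * bins_per_unit
        n_lad = int(round(spec.lad_fraction_true * n))
        labels = np.zeros(n, dtype=bool)
        if n_lad >= n:
            labels[:] = True
        elif n_lad > 0:
            k = max(1, int(round(n_lad / lad_run_bins)))
            # split n_lad LAD bins into k runs, interleaved with k+1 gaps
            run_sizes = np.full(k, n_lad // k)
            run_sizes[: n_lad % k] += 1
            gap_total = n - n_lad
            gap_sizes = np.full(k + 1, gap_total // (k + 1))
            gap_sizes[: gap_total % (k + 1)] += 1
            rng.shuffle(gap_sizes)
            pos = 0
            for run, gap in zip(run_sizes, gap_sizes[:k]):
                pos += int(gap)
                labels[pos : pos + int(run)] = True
                pos += int(run)
        log2oe = np.where(
            labels,
            rng.normal(mu_lad, sigma, size=n),
            rng.normal(mu_inter, sigma, size=n),
        )
        starts = np.arange(n, dtype=np.int64) * track_bin
        frames.append(
            pd.DataFrame(
                {
                    "chrom": spec.name,
                    "start": starts,
                    "end": starts + track_bin,
                    "log2oe": log2oe,
                    "is_lad_true": labels,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Mitotic-geometry fixtures


def _ngon_boundary_radius(theta: np.ndarray, radius: float, n_vertices: int) -> np.ndarray:
    """Boundary distance of a regular n-gon at angle theta (vertex at 0).

    Closed form for the distance from the centre to the polygon edge:
    R cos(pi/n) / cos(((theta) mod 2pi/n) - pi/n).
    """
    sector = 2.0 * np.pi / n_vertices
    phi = np.mod(theta, sector) - sector / 2.0
    return radius * np.cos(sector / 2.0) / np.cos(phi)


def make_geometry_battery(
    rng: np.random.Generator,
    n_points: int = 1000,
    radius_um: float = 10.0,
    n_vertices: int = 64,
) -> dict:
    """Labelled point battery for the shell/polar classifiers.

    The nucleus is a regular ``n_vertices``-gon of circumradius
    ``radius_um`` centred at a random offset; the two spindle poles sit
    at +/-0.4 R along a random axis.  Points are placed by closed-form
    polygon geometry at radial fractions safely away from the 2/3 shell
    boundary, with truth classes:

    * ``cen`` — inside the two innermost of three concentric shells
      (radial fraction <= 0.60 of the local boundary distance);
    * ``pol`` — peripheral (fraction >= 0.72) and projecting outside the
      closed pole-pole segment;
    * ``NPP`` — peripheral, projecting strictly between the pole planes.

    Returns dict with polygon vertices (closed ring not required), pole
    coordinates and a points table (x_um, y_um, true_class).
    """
    centre = rng.uniform(-30.0, 30.0, size=2)
    axis_angle = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.array([np.cos(axis_angle), np.sin(axis_angle)])
    poles = np.vstack(
        [centre - 0.4 * radius_um * axis, centre + 0.4 * radius_um * axis]
    )
    vert_theta = np.arange(n_vertices) * 2.0 * np.pi / n_vertices
    vertices = centre + radius_um * np.column_stack(
        [np.cos(vert_theta), np.sin(vert_theta)]
    )

    classes = rng.choice(["cen", "pol", "NPP"], size=n_points)
    pts = np.empty((n_points, 2))
    p1, p2 = poles
    seg = p2 - p1
    seg_len2 = float(seg @ seg)
    for i, cls in enumerate(classes):
        while True:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            if cls == "cen":
                frac = rng.uniform(0.05, 0.60)
            else:
                frac = rng.uniform(0.72, 0.95)
            rb = float(_ngon_boundary_radius(np.array([theta]), radius_um, n_vertices)[0])
            p = centre + frac * rb * np.array([np.cos(theta), np.sin(theta)])
            t = float((p - p1) @ seg) / seg_len2
            if cls == "cen":
                ok = True
            elif cls == "pol":
                ok = t < -0.03 or t > 1.03
            else:
                ok = 0.03 < t < 0.97
            if ok:
                pts[i] = p
                break
    points = pd.DataFrame(
        {"x_um": pts[:, 0], "y_um": pts[:, 1], "true_class": classes}
    )
    return {"vertices": vertices, "poles": poles, "points": points}


def make_outcome_battery(
    rng: np.random.Generator,
    n_cells: int = 200,
    pole_halfspan_um: float = 5.0,
) -> list[dict]:
    """Anaphase snapshots with known outcome labels.

    Each cell carries two poles, 15-24 kinetochore pairs segregating into
    two masses, plus at most one anomaly realizing the cell's truth
    label.  In the spindle frame (poles at +/-5 um on the x axis) the
    regions are separable with a margin relative to the default
    classification thresholds (midline half-width 1.5 um, pole-proximity
    radius 1.5 um):

    * mass kinetochores sit 1.7-3.0 um from the midplane on the plate
      side of their pole (so >= 2 um from the pole, outside the midline);
    * a lagging event is a single kinetochore within 1.3 um of the
      midplane, its partner in a mass;
    * a bridge is a well-separated pair (>1.2 um apart) with both
      kinetochores within 1.3 um of the midplane;
    * a misaligned pair has both kinetochores within 0.7 um of a pole.

    Coordinates are returned in a randomly rotated and translated frame.
    """
    cells = []
    labels = rng.choice(["no error", "lagging", "bridge", "misaligned"], size=n_cells)
    for ci, label in enumerate(labels):
        angle = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        shift = rng.uniform(-50.0, 50.0, size=2)
        poles_local = np.array(
            [[-pole_halfspan_um, 0.0], [pole_halfspan_um, 0.0]]
        )
        rows = []
        n_pairs = int(rng.integers(15, 25))
        for pid in range(n_pairs):
            for sign in (-1.0, 1.0):
                x = sign * rng.uniform(1.7, 3.0)
                y = rng.uniform(-2.0, 2.0)
                rows.append({"pair_id": pid, "x": x, "y": y})
        if label == "lagging":
            rows[0] = {"pair_id": n_pairs, "x": rng.uniform(-1.3, 1.3),
                       "y": rng.uniform(-1.5, 1.5)}
            rows[1]["pair_id"] = n_pairs
        elif label == "bridge":
            y0 = rng.uniform(-1.0, 1.0)
            rows[0] = {"pair_id": n_pairs, "x": rng.uniform(-1.3, -0.6), "y": y0}
            rows[1] = {"pair_id": n_pairs, "x": rng.uniform(0.6, 1.3), "y": y0}
        elif label == "misaligned":
            px = float(rng.choice([-1.0, 1.0])) * pole_halfspan_um
            for j in (0, 1):
                rows[j] = {"pair_id": n_pairs, "x": px + rng.uniform(-0.45, 0.45),
                           "y": rng.uniform(-0.45, 0.45)}
        kts = pd.DataFrame(rows)
        xy = (rot @ np.column_stack([kts["x"], kts["y"]]).T).T + shift
        kts = pd.DataFrame(
            {"pair_id": kts["pair_id"], "x_um": xy[:, 0], "y_um": xy[:, 1]}
        )
        poles = (rot @ poles_local.T).T + shift
        cells.append(
            {"cell_id": f"ana{ci:03d}", "kinetochores": kts,
             "poles": poles, "true_label": str(label)}
        )
    return cells
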