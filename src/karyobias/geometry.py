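"""Mitotic-geometry classification of kinetochore trajectories.

Operationalizes the live-imaging measurement rules:

* nuclear shell position at nuclear envelope breakdown (NEBD) — the
  hand-drawn nucleus outline is divided into three concentric shells by
  scaling the polygon about its centroid; a chromosome is *central* if
  it lies in the two innermost shells or touches the boundary of the
  second shell (i.e. inside or on the 2/3-scaled outline), else
  *peripheral*;
* polar status — a point is *polar* ("behind a spindle pole") when its
  projection onto the pole-pole axis falls outside the closed segment
  between the poles;
* spindle-elongation peak — the last frame of a continuous two-step
  increase in pole separation totalling more than 1 um;
* alignment time — minutes from NEBD until the kinetochore first stays
  within ``plate_halfwidth`` of the equatorial plane (the perpendicular
  bisector of the pole axis) for at least three consecutive frames;
* anaphase outcome — no error / lagging / bridge / misaligned, decided
  from kinetochore-pair positions relative to the two segregating
  masses and the poles; multipolar cells are excluded upstream;
* expected-vs-observed misalignment — the fraction of polar pairs at
  NEBD predicts the fraction of unaligned chromosomes that are polar;
  tested with Fisher's exact test on the 2x2 of polar x unaligned.

All rules are purely 2D (maximum-intensity projection coordinates) and
invariant under rigid motions of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point, Polygon

from .stats import fisher_two_sided

__all__ = [
    "GeometryParams",
    "shell_class",
    "polar_class",
    "position_category",
    "elongation_peak",
    "alignment_time",
    "classify_outcome",
    "expected_vs_observed",
]


@dataclass(frozen=True)
class GeometryParams:
    """Thresholds of the geometric classification rules (um / frames)."""

    n_shells: int = 3
    central_shells: int = 2
    elongation_delta_um: float = 1.0
    elongation_rule: str = "sum"  # "sum" | "per_step"
    plate_halfwidth_um: float = 1.5
    align_persist_frames: int = 3
    frame_interval_s: float = 20.0
    midline_halfwidth_um: float = 1.5
    pole_radius_um: float = 1.5
    bridge_min_separation_um: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.central_shells < self.n_shells:
            raise ValueError("need 0 < central_shells < n_shells")
        if self.elongation_rule not in ("sum", "per_step"):
            raise ValueError("elongation_rule must be 'sum' or 'per_step'")
        for f in ("elongation_delta_um", "plate_halfwidth_um",
                  "frame_interval_s", "midline_halfwidth_um",
                  "pole_radius_um"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _as_polygon(polygon) -> Polygon:
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("nucleus outline must be a simple polygon with area")
    return poly


def shell_class(point, polygon, params: GeometryParams | None = None) -> str:
    """'central' or 'peripheral' by the concentric-shell rule.

    The outline is scaled about its centroid by
    ``central_shells / n_shells`` (2/3 by default); points inside or on
    the scaled boundary are central ("touching" counts as central).
    For a circular nucleus this reduces to a radius threshold at 2/3 R.
    """
    params = params or GeometryParams()
    poly = _as_polygon(polygon)
    factor = params.central_shells / params.n_shells
    inner = affinity.scale(
        poly, xfact=factor, yfact=factor, origin=poly.centroid
    )
    p = Point(float(point[0]), float(point[1]))
    # covers() handles interior + boundary; the distance fallback keeps
    # "touching" robust to floating-point ties on the scaled outline
    tol = 1e-9 * np.sqrt(poly.area)
    return (
        "central"
        if inner.covers(p) or inner.exterior.distance(p) <= tol
        else "peripheral"
    )


def _axis_projection(point, pole1, pole2) -> float:
    """Scalar projection of point onto the pole axis, 0 at pole1, 1 at pole2."""
    p1 = np.asarray(pole1, dtype=float)
    p2 = np.asarray(pole2, dtype=float)
    axis = p2 - p1
    norm2 = float(axis @ axis)
    if norm2 == 0:
        raise ValueError("coincident spindle poles")
    return float((np.asarray(point, dtype=float) - p1) @ axis) / norm2


def polar_class(point, pole1, pole2) -> str:
    """'polar' iff the axis projection falls outside the closed segment."""
    t = _axis_projection(point, pole1, pole2)
    return "polar" if (t < 0.0 or t > 1.0) else "non-polar"


def position_category(point, polygon, pole1, pole2,
                      params: GeometryParams | None = None) -> str:
    """Three-way class: 'cen' (central), 'pol' (peripheral behind a
    pole) or 'NPP' (peripheral between the pole planes)."""
    if shell_class(point, polygon, params) == "central":
        return "cen"
    return "pol" if polar_class(point, pole1, pole2) == "polar" else "NPP"


def elongation_peak(
    pole_distances, params: GeometryParams | None = None
) -> int | None:
    """Frame of the prometaphase spindle-elongation peak.

    The last frame t whose two preceding steps both increase the pole
    separation and (under the default "sum" rule) together add more than
    ``elongation_delta_um``; the "per_step" variant requires each step
    alone to exceed the threshold.  Returns None when no frame
    qualifies.
    """
    params = params or GeometryParams()
    d = np.asarray(pole_distances, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 frames")
    steps = np.diff(d)
    best: int | None = None
    for t in range(2, d.size):
        s1, s2 = steps[t - 2], steps[t - 1]
        if s1 <= 0 or s2 <= 0:
            continue
        if params.elongation_rule == "sum":
            ok = s1 + s2 > params.elongation_delta_um
        else:
            ok = min(s1, s2) > params.elongation_delta_um
        if ok:
            best = t
    return best


def _plate_distance(points: np.ndarray, pole1, pole2) -> np.ndarray:
    """Distance of each point from the equatorial plane, along the axis."""
    p1 = np.asarray(pole1, dtype=float)
    p2 = np.asarray(pole2, dtype=float)
    axis = p2 - p1
    length = float(np.linalg.norm(axis))
    if length == 0:
        raise ValueError("coincident spindle poles")
    unit = axis / length
    mid = (p1 + p2) / 2.0
    return np.abs((np.asarray(points, dtype=float) - mid) @ unit)


def alignment_time(
    track_xy: np.ndarray,
    poles_xy: np.ndarray,
    nebd_frame: int,
    params: GeometryParams | None = None,
) -> float | None:
    """Minutes from NEBD to stable arrival at the metaphase plate.

    ``track_xy`` is (n_frames, 2); ``poles_xy`` is (n_frames, 2, 2)
    holding both pole positions per frame.  Alignment is the first frame
    from which the kinetochore stays within ``plate_halfwidth_um`` of
    the equatorial plane for ``align_persist_frames`` consecutive
    frames; a transient crossing does not count.  Returns None when the
    track never aligns.
    """
    params = params or GeometryParams()
    track = np.asarray(track_xy, dtype=float)
    poles = np.asarray(poles_xy, dtype=float)
    if track.ndim != 2 or track.shape[0] != poles.shape[0]:
        raise ValueError("track and pole arrays must cover the same frames")
    if not 0 <= nebd_frame < track.shape[0]:
        raise ValueError("NEBD frame outside the track")
    dist = np.array(
        [
            _plate_distance(track[i : i + 1], poles[i, 0], poles[i, 1])[0]
            for i in range(track.shape[0])
        ]
    )
    within = dist <= params.plate_halfwidth_um
    k = params.align_persist_frames
    for f in range(nebd_frame, track.shape[0] - k + 1):
        if within[f : f + k].all():
            return (f - nebd_frame) * params.frame_interval_s / 60.0
    return None


def classify_outcome(
    kinetochores: pd.DataFrame,
    poles: np.ndarray,
    params: GeometryParams | None = None,
) -> str:
    """Anaphase outcome of one cell: no error / lagging / bridge / misaligned.

    ``kinetochores`` has columns pair_id, x_um, y_um (positions at early
    anaphase); ``poles`` is (2, 2).  Rules, applied per kinetochore
    pair on axis-projected coordinates:

    * bridge — both kinetochores of a pair within
      ``midline_halfwidth_um`` of the equatorial plane and more than
      ``bridge_min_separation_um`` apart (well separated but stuck
      between the masses);
    * lagging — exactly one kinetochore of a pair at the midline, its
      partner having segregated (a single stuck, stretched kinetochore);
    * misaligned — both kinetochores within ``pole_radius_um`` of a
      spindle pole;
    * no error — none of the above.

    Cells with more than two poles must be excluded before calling.
    """
    params = params or GeometryParams()
    poles = np.asarray(poles, dtype=float)
    if poles.shape != (2, 2):
        raise ValueError("exactly two poles required (multipolar cells excluded)")
    pts = kinetochores[["x_um", "y_um"]].to_numpy(dtype=float)
    mid_dist = _plate_distance(pts, poles[0], poles[1])
    at_mid = mid_dist <= params.midline_halfwidth_um
    pole_dist = np.minimum(
        np.linalg.norm(pts - poles[0], axis=1),
        np.linalg.norm(pts - poles[1], axis=1),
    )
    at_pole = pole_dist <= params.pole_radius_um
    has_lagging = has_bridge = has_misaligned = False
    for _, idx in kinetochores.groupby("pair_id").indices.items():
        mids = at_mid[idx]
        if len(idx) >= 2 and mids.sum() >= 2:
            sep = float(
                np.linalg.norm(pts[idx[0]] - pts[idx[1]])
            )
            if sep > params.bridge_min_separation_um:
                has_bridge = True
                continue
        if mids.sum() == 1:
            has_lagging = True
        if len(idx) >= 2 and at_pole[idx].all():
            has_misaligned = True
    if has_bridge:
        return "bridge"
    if has_lagging:
        return "lagging"
    if has_misaligned:
        return "misaligned"
    return "no error"


def expected_vs_observed(
    polar_at_nebd: int,
    total_pairs: int,
    unaligned_at_metaphase: int,
    observed_polar_unaligned: int,
) -> dict:
    """Expected vs observed share of unaligned chromosomes that are polar.

    The expected percentage is the polar fraction at NEBD (if polar
    status carried no risk, unaligned chromosomes would be polar at that
    base rate); the observed percentage is the polar fraction among
    chromosomes unaligned at the start of metaphase.  Significance by
    two-sided Fisher's exact test on polar status x unaligned status.
    """
    if not (0 <= observed_polar_unaligned <= unaligned_at_metaphase
            <= total_pairs):
        raise ValueError("inconsistent counts")
    if observed_polar_unaligned > polar_at_nebd or polar_at_nebd > total_pairs:
        raise ValueError("inconsistent counts")
    if unaligned_at_metaphase == 0:
        raise ValueError("no unaligned chromosomes: observed share undefined")
    a = observed_polar_unaligned
    b = polar_at_nebd - a
    c = unaligned_at_metaphase - a
    d = total_pairs - polar_at_nebd - c
    return {
        "expected_percent": 100.0 * polar_at_nebd / total_pairs,
        "observed_percent": 100.0 * a / unaligned_at_metaphase,
        "fisher_p": fisher_two_sided(a, b, c, d),
    }
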