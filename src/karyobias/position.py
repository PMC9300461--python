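"""Nuclear-position correlates: radial distance and LAD fractions.

Two independent measures of how peripheral a chromosome sits in the
interphase nucleus:

* imaging — the centroid of a FISH probe signal relative to the centre
  of mass of the nucleus, normalized by the nucleus' equivalent radius
  sqrt(area/pi), giving a relative radial distance in [0, ~1];
* genomics — the fraction of a chromosome's 100-kb bins called
  lamina-associated (LAD) from a DamID-style log2(observed/expected)
  lamina-contact track.  LAD calling is a transparent threshold rule:
  bins with log2(OE) > 0 are candidates, runs shorter than ``min_run``
  are dropped, then gaps shorter than ``min_run`` between surviving
  runs are bridged.

Either measure can be correlated against a cohort's per-chromosome
error shares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import pearson_r_p

__all__ = [
    "centroid",
    "radial_distance",
    "lad_call",
    "lad_percent",
    "position_error_correlation",
]


def centroid(pixels: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Intensity-weighted centre of mass of a 2D pixel set.

    ``pixels`` is (n, 2) coordinates; ``weights`` defaults to uniform.
    """
    pts = np.asarray(pixels, dtype=float)
    if pts.size == 0:
        raise ValueError("empty pixel set")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("pixels must be an (n, 2) array")
    if weights is None:
        return pts.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if w.shape != (pts.shape[0],) or w.sum() <= 0:
        raise ValueError("weights must be positive and match pixels")
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def radial_distance(
    probe_centroid: np.ndarray,
    nucleus_pixels: np.ndarray,
    nucleus_weights: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> dict:
    """Probe distance from the nucleus centre of mass.

    Returns both the absolute distance in micrometres and the relative
    distance normalized by the nucleus' equivalent radius
    sqrt(area / pi), where the area is the pixel count times the pixel
    area.  A probe at the centre scores 0; on the boundary of a circular
    nucleus, ~1.
    """
    pts = np.asarray(nucleus_pixels, dtype=float)
    if pts.size == 0:
        raise ValueError("zero-area nucleus")
    centre = centroid(pts, nucleus_weights)
    d_px = float(np.linalg.norm(np.asarray(probe_centroid, dtype=float) - centre))
    area_um2 = pts.shape[0] * pixel_size_um**2
    r_equiv = float(np.sqrt(area_um2 / np.pi))
    if r_equiv <= 0:
        raise ValueError("zero-area nucleus")
    return {
        "distance_um": d_px * pixel_size_um,
        "relative": d_px * pixel_size_um / r_equiv,
        "equivalent_radius_um": r_equiv,
    }


def _filter_runs(
    labels: np.ndarray, min_run: int, value: bool, interior_only: bool = False
) -> np.ndarray:
    """Set runs of ``value`` shorter than min_run to the opposite value.

    With ``interior_only`` runs touching either end of the array are
    left alone (used for gap bridging: only gaps *between* LAD runs are
    bridged, not chromosome ends).
    """
    out = labels.copy()
    n = out.size
    i = 0
    while i < n:
        if out[i] != value:
            i += 1
            continue
        j = i
        while j < n and out[j] == value:
            j += 1
        if j - i < min_run and not (interior_only and (i == 0 or j == n)):
            out[i:j] = not value
        i = j
    return out


def lad_call(
    track: pd.DataFrame, min_run: int = 3, threshold: float = 0.0
) -> pd.Series:
    """Boolean LAD labels per track bin.

    Bins with log2(OE) above ``threshold`` are LAD candidates; per
    chromosome, candidate runs shorter than ``min_run`` bins are removed,
    then sub-``min_run`` gaps between surviving runs are bridged.
    The track must have columns chrom, start, log2oe and be sorted by
    (chrom, start).
    """
    labels = np.zeros(len(track), dtype=bool)
    for _, idx in track.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        starts = track["start"].to_numpy()[idx]
        if np.any(np.diff(starts) <= 0):
            raise ValueError("track bins must be sorted and non-overlapping")
        cand = track["log2oe"].to_numpy()[idx] > threshold
        cand = _filter_runs(cand, min_run, value=True)
        if cand.any():
            cand = _filter_runs(cand, min_run, value=False, interior_only=True)
        labels[idx] = cand
    return pd.Series(labels, index=track.index, name="is_lad")


def lad_percent(track: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Percent of LAD bins per chromosome."""
    df = track.assign(is_lad=labels.to_numpy())
    pct = df.groupby("chrom", sort=False)["is_lad"].mean() * 100.0
    return pct.rename("lad_percent")


def position_error_correlation(
    shares: pd.Series, position_metric: pd.Series
) -> tuple[float, float]:
    """Pearson r, p between error shares and a per-chromosome position metric.

    The two series must cover the same chromosomes (order-insensitive).
    """
    if set(shares.index) != set(position_metric.index):
        raise ValueError("chromosome sets differ")
    aligned = position_metric.reindex(shares.index)
    return pearson_r_p(shares.to_numpy(), aligned.to_numpy())
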