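"""Quantification of polymer-ensemble geometry and contacts.

All routines operate on bead coordinates in dimensionless sigma units and
on symmetric contact maps.  Physical scales come from the calibration
helpers: pairwise FISH distances fix the nm-per-sigma factor (44 nm for the
published locus) and projected overlaps fix a dimensionless geometric
factor (1.2 in the published comparison).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .polymer.model import Trajectory

_EDGE_TOL = 1e-12

ArrayLike = Union[np.ndarray, Sequence[float]]
FrameSource = Union[Trajectory, np.ndarray]


@dataclass(frozen=True)
class RegionSet:
    """Named bead-index intervals (half-open) on one polymer."""

    regions: Dict[str, Tuple[int, int]]
    n_beads: int

    def __post_init__(self):
        for name, (a, b) in self.regions.items():
            if not (0 <= a < b <= self.n_beads):
                raise ValueError(f"region {name!r} ({a},{b}) outside "
                                 f"[0,{self.n_beads})")

    def slice(self, name: str) -> slice:
        a, b = self.regions[name]
        return slice(a, b)

    def names(self) -> List[str]:
        return list(self.regions)


def _bead_frames(source: FrameSource) -> np.ndarray:
    """(n_frames, n_beads, 3) bead coordinates from a trajectory or array."""
    if isinstance(source, Trajectory):
        return source.bead_frames
    arr = np.asarray(source, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected (n_frames, n_beads, 3) coordinates")
    return arr


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def contact_map(ensemble: Iterable[FrameSource], threshold: float = 7.5) -> np.ndarray:
    """Ensemble contact frequency map.

    Entry (i, j) is the fraction, over every sampled frame of every
    independent simulation, of frames in which beads i and j lie closer
    than ``threshold`` (default 7.5 sigma).  The diagonal is 1 by the
    self-contact convention.
    """
    total = None
    n_frames = 0
    for source in ensemble:
        frames = _bead_frames(source)
        for f in frames:
            d = squareform(pdist(f))
            c = (d < threshold).astype(float)
            total = c if total is None else total + c
        n_frames += frames.shape[0]
    if total is None or n_frames == 0:
        raise ValueError("empty ensemble")
    m = total / n_frames
    np.fill_diagonal(m, 1.0)
    return m


def subtraction_map(map_ne: np.ndarray, map_bulk: np.ndarray) -> np.ndarray:
    """Bin-wise difference D = x_NE - x_bulk between two contact maps."""
    a = np.asarray(map_ne, float)
    b = np.asarray(map_bulk, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a - b


def map_correlation(model_map: np.ndarray, exp_map: np.ndarray,
                    min_genomic_distance: int = 100_000,
                    bin_size: int = 20_000) -> Tuple[float, float]:
    """Pearson r and distance-corrected Pearson r' between two maps.

    Only upper-triangle entries at genomic distance strictly greater than
    ``min_genomic_distance`` enter.  The distance correction subtracts each
    genomic-distance diagonal's mean from both maps (observed minus expected
    by distance) before correlating.
    """
    a = np.asarray(model_map, float)
    b = np.asarray(exp_map, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("maps must be square and same shape")
    n = a.shape[0]
    i, j = np.triu_indices(n, k=1)
    sep = (j - i) * bin_size
    keep = sep > min_genomic_distance
    if keep.sum() < 10:
        raise ValueError("fewer than 10 eligible entries above distance cut")
    i, j = i[keep], j[keep]
    r = float(np.corrcoef(a[i, j], b[i, j])[0, 1])

    def _detrend(m):
        out = m.copy()
        for d in range(1, n):
            di = np.arange(n - d)
            out[di, di + d] -= m[di, di + d].mean()
            out[di + d, di] = out[di, di + d]
        return out

    ad, bd = _detrend(a), _detrend(b)
    rp = float(np.corrcoef(ad[i, j], bd[i, j])[0, 1])
    return r, rp


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distance(traj: FrameSource, region_a: Tuple[int, int],
                      region_b: Tuple[int, int],
                      last_k: int = 20) -> Tuple[float, np.ndarray]:
    """Centre-of-mass distance between two bead regions.

    Per frame the distance between the centres of mass of the beads in each
    region; returns (mean over the last ``last_k`` frames, per-frame array).
    """
    frames = _bead_frames(traj)
    if frames.shape[0] < last_k:
        raise ValueError(f"trajectory has {frames.shape[0]} frames < {last_k}")
    (a0, a1), (b0, b1) = region_a, region_b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("empty region")
    com_a = frames[:, a0:a1].mean(axis=1)
    com_b = frames[:, b0:b1].mean(axis=1)
    d = np.linalg.norm(com_a - com_b, axis=1)
    return float(d[-last_k:].mean()), d


def ne_distance(coords: np.ndarray, region: Tuple[int, int],
                radius: float = 40.0,
                center: Sequence[float] = (0.0, 0.0, 0.0)) -> float:
    """Distance of a region's centre of mass from the NE sphere:
    d_NE = R - |r_CM - r_NE|  (sigma units)."""
    a, b = region
    if b <= a:
        raise ValueError("empty region")
    coords = np.asarray(coords, float)
    com = coords[a:b].mean(axis=0)
    return float(radius - np.linalg.norm(com - np.asarray(center, float)))


def calibrate_length(model_medians: ArrayLike, exp_medians: ArrayLike) -> float:
    """nm-per-sigma mapping factor: for each probe pair equalise the model
    and experimental median distances, then average the per-pair ratios."""
    m = np.asarray(model_medians, float)
    e = np.asarray(exp_medians, float)
    if m.shape != e.shape or m.size == 0:
        raise ValueError("median lists must be equal-length and non-empty")
    if (m <= 0).any():
        raise ValueError("model medians must be positive")
    return float(np.mean(e / m))


def calibrate_overlap(model_overlap_medians: ArrayLike,
                      exp_overlap_medians: ArrayLike) -> float:
    """Geometric mapping factor for overlap values (same mean-of-ratios
    contract as the length calibration)."""
    return calibrate_length(model_overlap_medians, exp_overlap_medians)


# ---------------------------------------------------------------------------
# projected circle overlaps
# ---------------------------------------------------------------------------

def circle_intersection_area(r1: float, r2: float, d: float) -> float:
    """Area of intersection of two circles at centre distance d.

    Piecewise: 0 when d >= r1 + r2 (disjoint, with 1e-12 slack at the
    boundary), pi*min(r1,r2)^2 when d <= |r1 - r2| (containment), else the
    two-segment lens formula
    A12 = r2^2*a1 - d1*sqrt(r2^2 - d1^2) + r1^2*a2 - d2*sqrt(r1^2 - d2^2)
    with d1 = (r2^2 - r1^2 + d^2) / (2 d), d2 = d - d1,
    a1 = arccos(d1/r2), a2 = arccos(d2/r1).
    """
    if r1 < 0 or r2 < 0 or d < 0:
        raise ValueError("radii and distance must be non-negative")
    if d >= r1 + r2 - _EDGE_TOL:
        return 0.0
    if d <= abs(r2 - r1) + _EDGE_TOL:
        rm = min(r1, r2)
        return float(np.pi * rm * rm)
    d1 = (r2 * r2 - r1 * r1 + d * d) / (2 * d)
    d2 = d - d1
    a1 = np.arccos(np.clip(d1 / r2, -1.0, 1.0))
    a2 = np.arccos(np.clip(d2 / r1, -1.0, 1.0))
    return float(r2 * r2 * a1 - d1 * np.sqrt(max(r2 * r2 - d1 * d1, 0.0))
                 + r1 * r1 * a2 - d2 * np.sqrt(max(r1 * r1 - d2 * d2, 0.0)))


def _project(coords: np.ndarray, axis: str) -> np.ndarray:
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    keep = [k for k in range(3) if k != ax]
    return np.asarray(coords, float)[:, keep]


def _circle_of(points2d: np.ndarray) -> Tuple[np.ndarray, float]:
    """Centre and 2D gyration radius of projected coordinates."""
    c = points2d.mean(axis=0)
    rg = float(np.sqrt(((points2d - c) ** 2).sum(axis=1).mean()))
    return c, rg


def projected_overlap(coords_a: np.ndarray, coords_b: np.ndarray,
                      axis: str = "z", tol: float = 1e-9) -> float:
    """Projected pairwise overlap: overlap12 = A12 / (A1 + A2 - A12).

    Coordinates are projected on the plane perpendicular to ``axis``; each
    projection is approximated as a circle whose radius is the 2D gyration
    radius, and the circle-intersection area gives A12.  Degenerate
    zero-radius regions yield 0 unless both centres coincide (-> 1).
    """
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise ValueError("empty region")
    ca, r1 = _circle_of(_project(coords_a, axis))
    cb, r2 = _circle_of(_project(coords_b, axis))
    d = float(np.linalg.norm(ca - cb))
    if r1 <= tol or r2 <= tol:
        return 1.0 if (d <= tol and r1 <= tol and r2 <= tol) else 0.0
    a1 = np.pi * r1 * r1
    a2 = np.pi * r2 * r2
    a12 = circle_intersection_area(r1, r2, d)
    return float(a12 / (a1 + a2 - a12))


def three_body_overlap(coords_1: np.ndarray, coords_2: np.ndarray,
                       coords_3: np.ndarray, axis: str = "z") -> float:
    """Three-body projected overlap of a focal object with two partners:
    overlap123 = (A12 + A13) / (A1 + A2 + A3 - A12 - A13 - A23)."""
    circles = []
    for coords in (coords_1, coords_2, coords_3):
        if len(coords) == 0:
            raise ValueError("empty region")
        circles.append(_circle_of(_project(coords, axis)))
    (c1, r1), (c2, r2), (c3, r3) = circles
    a = [np.pi * r * r for r in (r1, r2, r3)]
    a12 = circle_intersection_area(r1, r2, float(np.linalg.norm(c1 - c2)))
    a13 = circle_intersection_area(r1, r3, float(np.linalg.norm(c1 - c3)))
    a23 = circle_intersection_area(r2, r3, float(np.linalg.norm(c2 - c3)))
    den = a[0] + a[1] + a[2] - a12 - a13 - a23
    if den <= 0:
        raise ValueError(f"degenerate denominator {den} "
                         f"(areas {a}, intersections {a12},{a13},{a23})")
    return float((a12 + a13) / den)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def sphericity(coords: np.ndarray) -> float:
    """Convex-hull sphericity: pi^(1/3) (6V)^(2/3) / A, 1 for a ball."""
    pts = np.asarray(coords, float)
    if pts.shape[0] < 4:
        raise ValueError("need >= 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate point set: {exc}") from exc
    if hull.volume <= 0:
        raise ValueError("coplanar point set has zero hull volume")
    return float(np.pi ** (1 / 3) * (6 * hull.volume) ** (2 / 3) / hull.area)


def radius_of_gyration(coords: np.ndarray) -> float:
    pts = np.asarray(coords, float)
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum(axis=1).mean()))


def wall_contact_fraction(frames: FrameSource, radius: float = 40.0,
                          cutoff: float = 2.5,
                          bead_mask: Union[np.ndarray, None] = None) -> float:
    """Fraction of (bead, frame) pairs within ``cutoff`` of the NE wall."""
    arr = _bead_frames(frames)
    if bead_mask is not None:
        arr = arr[:, np.asarray(bead_mask, bool), :]
    r = np.linalg.norm(arr, axis=2)
    return float((radius - r < cutoff).mean())
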