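"""Point-pattern containers, coordinate-table I/O, and edge correction.

Immunogold coordinates are digitized from transmission-EM micrographs of
intact plasma-membrane sheets, typically within a 1 um^2 (1000 x 1000 nm)
analysis window. This module provides the rectangular study region, the
point-pattern containers shared by all estimators, CSV/TSV readers for
externally produced coordinate tables, and the isotropic edge-correction
weight ``w_ij`` — the reciprocal of the fraction of the circumference of
the circle centered on one point and passing through another that lies
inside the study window. The weight compensates pair counts near the
window boundary for neighbours that fall outside the observed area.

All coordinates are continuous lengths in nanometres with the origin at
the lower-left corner of the region; distances are Euclidean. The region
is closed: points exactly on the boundary belong to the pattern.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyRegion",
    "PointPattern",
    "BivariatePattern",
    "RadiusGrid",
    "read_point_table",
    "write_results_table",
    "edge_correction_weight",
    "circle_inside_fraction",
    "PointPatternError",
    "InsufficientPointsError",
]

_TWO_PI = 2.0 * np.pi
#: angular samples for the numerical fallback when a circle exits the
#: window through two opposite edges (no simple closed form).
_N_ARC_SAMPLES = 4096


class PointPatternError(ValueError):
    """Invalid point pattern, region, or estimator input."""


class InsufficientPointsError(PointPatternError):
    """Too few points for the requested estimator."""


@dataclass(frozen=True)
class StudyRegion:
    """Rectangular observation window, lengths in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise PointPatternError(
                f"degenerate region: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @classmethod
    def from_size(cls, width: float, height: float | None = None) -> "StudyRegion":
        """Region ``[0, width] x [0, height]`` (square if height omitted)."""
        if height is None:
            height = width
        return cls(0.0, 0.0, float(width), float(height))

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Window area A in nm^2."""
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the (k, 2) coordinates lie in the closed region."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )


@dataclass(frozen=True)
class PointPattern:
    """Gold-particle coordinates (nm) observed inside a study region.

    ``points`` is an (n, 2) float array; the region is closed, so
    digitized particles sitting exactly on the window edge are kept.
    """

    points: np.ndarray
    region: StudyRegion
    channel: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise PointPatternError(f"points must be (n, 2), got shape {pts.shape}")
        inside = self.region.contains(pts) if len(pts) else np.ones(0, bool)
        if not bool(np.all(inside)):
            bad = int(np.flatnonzero(~inside)[0])
            raise PointPatternError(
                f"point {bad} at {tuple(pts[bad])} lies outside the region"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def with_points(self, points: np.ndarray) -> "PointPattern":
        return dataclasses.replace(self, points=points)


@dataclass(frozen=True)
class BivariatePattern:
    """Paired big-gold (6 nm, GFP) / small-gold (2 nm, RFP) patterns on one region."""

    big: PointPattern
    small: PointPattern

    def __post_init__(self) -> None:
        if self.big.region != self.small.region:
            raise PointPatternError("big and small channels must share one region")

    @property
    def region(self) -> StudyRegion:
        return self.big.region

    @property
    def n_b(self) -> int:
        return self.big.n

    @property
    def n_s(self) -> int:
        return self.small.n

    def swapped(self) -> "BivariatePattern":
        return BivariatePattern(big=self.small, small=self.big)


def _default_radii() -> np.ndarray:
    return np.arange(1.0, 241.0)


@dataclass(frozen=True)
class RadiusGrid:
    """Strictly increasing positive radii (nm); default 1, 2, ..., 240 nm."""

    radii: np.ndarray = field(default_factory=_default_radii)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float).ravel()
        if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise PointPatternError("radii must be strictly increasing and positive")
        object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])

    @classmethod
    def from_spec(cls, start: float = 1.0, stop: float = 240.0, step: float = 1.0) -> "RadiusGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


# ---------------------------------------------------------------------------
# Coordinate-table I/O
# ---------------------------------------------------------------------------

_X_ALIASES = ("x", "X", "x_nm", "X_nm", "xm", "X (px)")
_Y_ALIASES = ("y", "Y", "y_nm", "Y_nm", "ym", "Y (px)")


def _find_column(columns: list[str], aliases: tuple[str, ...], kind: str, path) -> str:
    lowered = {str(c).strip().lower(): c for c in columns}
    for alias in aliases:
        if alias.lower() in lowered:
            return lowered[alias.lower()]
    raise PointPatternError(
        f"{path}: no {kind!r} coordinate column among {list(columns)}"
    )


def read_point_table(
    path,
    region: StudyRegion,
    pixel_size: float = 1.0,
    channel: str = "",
) -> PointPattern:
    """Read a delimited (CSV/TSV) coordinate table into a :class:`PointPattern`.

    Accepts lower-case ``x, y`` headers or ImageJ-style ``X, Y``; coordinates
    are multiplied by ``pixel_size`` (nm per pixel, 1 for tables already in
    nm). Every converted point must lie inside the closed region.
    """
    if pixel_size <= 0:
        raise PointPatternError(f"pixel_size must be > 0, got {pixel_size}")
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        return PointPattern(np.empty((0, 2)), region, channel)
    if table.empty:
        return PointPattern(np.empty((0, 2)), region, channel)
    xcol = _find_column(list(table.columns), _X_ALIASES, "x", path)
    ycol = _find_column(list(table.columns), _Y_ALIASES, "y", path)
    xy = table[[xcol, ycol]].to_numpy()
    try:
        xy = xy.astype(float)
    except (TypeError, ValueError) as exc:
        raise PointPatternError(f"{path}: non-numeric coordinates: {exc}") from None
    if np.isnan(xy).any():
        bad = int(np.flatnonzero(np.isnan(xy).any(axis=1))[0])
        raise PointPatternError(f"{path}: missing coordinate in row {bad}")
    xy = xy * float(pixel_size)
    inside = region.contains(xy)
    if not bool(np.all(inside)):
        bad = int(np.flatnonzero(~inside)[0])
        raise PointPatternError(
            f"{path}: row {bad} converts to {tuple(xy[bad])} nm, outside the region"
        )
    return PointPattern(xy, region, channel)


def write_point_table(pattern: PointPattern, path) -> None:
    """Write a pattern back to CSV (nm coordinates, ``x,y`` header)."""
    pd.DataFrame({"x": pattern.x, "y": pattern.y}).to_csv(path, index=False)


def write_results_table(records, path) -> None:
    """Write homogeneous tabular results (list of dicts or DataFrame) to CSV."""
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if frame.empty:
        raise PointPatternError("refusing to write an empty results table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Edge correction
# ---------------------------------------------------------------------------

def circle_inside_fraction(cx, cy, r, region: StudyRegion) -> np.ndarray:
    """Fraction of the circumference of circle(center, r) inside the window.

    Vectorized over centers/radii. Uses the exact closed form for a
    rectangular window built from the per-edge exterior arcs
    ``2*arccos(d_e/r)`` with right-angle corner overlaps removed by
    inclusion–exclusion; circles exiting through two opposite edges fall
    back to uniform angular sampling of the circumference.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    r = np.asarray(r, dtype=float)
    cx, cy, r = np.broadcast_arrays(cx, cy, r)
    scalar = cx.ndim == 0
    cx, cy, r = cx.ravel(), cy.ravel(), r.ravel()

    d_l = cx - region.x_min
    d_r = region.x_max - cx
    d_b = cy - region.y_min
    d_t = region.y_max - cy
    if np.any(d_l < 0) or np.any(d_r < 0) or np.any(d_b < 0) or np.any(d_t < 0):
        raise PointPatternError("circle center outside the study region")
    if np.any(r <= 0):
        raise PointPatternError("edge-correction radius must be > 0")

    # half exterior angle per edge; 0 when the edge is beyond the circle
    a_l = np.arccos(np.clip(d_l / r, 0.0, 1.0))
    a_r = np.arccos(np.clip(d_r / r, 0.0, 1.0))
    a_b = np.arccos(np.clip(d_b / r, 0.0, 1.0))
    a_t = np.arccos(np.clip(d_t / r, 0.0, 1.0))

    exterior = 2.0 * (a_l + a_r + a_b + a_t)
    half_pi = 0.5 * np.pi
    # corner overlap: the arc beyond both adjacent edges is counted twice
    for a1, a2 in ((a_l, a_b), (a_l, a_t), (a_r, a_b), (a_r, a_t)):
        exterior -= np.maximum(0.0, a1 + a2 - half_pi)
    frac = 1.0 - exterior / _TWO_PI

    opposite = ((d_l < r) & (d_r < r)) | ((d_b < r) & (d_t < r))
    if np.any(opposite):
        theta = _TWO_PI * (np.arange(_N_ARC_SAMPLES) + 0.5) / _N_ARC_SAMPLES
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        for k in np.flatnonzero(opposite):
            px = cx[k] + r[k] * cos_t
            py = cy[k] + r[k] * sin_t
            inside = (
                (px >= region.x_min)
                & (px <= region.x_max)
                & (py >= region.y_min)
                & (py <= region.y_max)
            )
            frac[k] = inside.mean()

    frac = np.clip(frac, 0.0, 1.0)
    return float(frac[0]) if scalar else frac


def edge_correction_weight(center, r: float, region: StudyRegion) -> float:
    """Ripley isotropic edge weight ``w >= 1`` for one circle.

    ``w`` is the reciprocal of the circumference fraction of the circle of
    radius ``r`` centered at ``center`` that lies inside the window; it is
    exactly 1 for fully interior circles.
    """
    center = np.asarray(center, dtype=float)
    frac = circle_inside_fraction(center[0], center[1], float(r), region)
    if frac <= 0.0:
        raise PointPatternError(
            f"circle at {tuple(center)} with r={r} has no circumference inside the region"
        )
    return 1.0 / frac


def pair_weights(centers: np.ndarray, radii: np.ndarray, region: StudyRegion) -> np.ndarray:
    """Vector of edge weights for circles centered at ``centers`` with per-pair radii."""
    if len(centers) == 0:
        return np.empty(0)
    frac = circle_inside_fraction(centers[:, 0], centers[:, 1], radii, region)
    frac = np.atleast_1d(frac)
    if np.any(frac <= 0.0):
        raise PointPatternError("edge weight undefined: circumference entirely outside")
    return 1.0 / frac
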