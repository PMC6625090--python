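"""Auxiliary scalar quantifications used alongside the spatial statistics.

Four small, unrelated readouts share this module: AFM surface roughness
R_q (RMS height deviation from the leveled image plane, the curvature
proxy for intact apical membranes), donor-lifetime FRET efficiency
(E = 1 - tau_DA / tau_D, reporting oligomerization in membrane
vesicles), the nanobar end/center fluorescence-intensity ratio (the
curvature-preference readout on nanopatterned substrates, with rolling-
ball-style background subtraction and averaged heat maps), and
surface-plasmon-resonance binding-isotherm assembly (RU_S / RU_L versus
protein concentration, grouped by liposome diameter).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import disk, opening

__all__ = [
    "HeightMap",
    "FretMeasurement",
    "NanobarGeometry",
    "SPRRecord",
    "rq_roughness",
    "fret_efficiency",
    "nanobar_end_center_ratio",
    "nanobar_masks",
    "nanobar_heatmap",
    "subtract_background",
    "spr_binding_table",
]


class MetricsError(ValueError):
    """Invalid imaging-metric input."""


@dataclass(frozen=True)
class HeightMap:
    """AFM topography: 2-D grid of heights (nm) with square pixels."""

    heights: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.shape[0] < 2 or h.shape[1] < 2:
            raise MetricsError(f"height map must be at least 2x2, got {h.shape}")
        if not np.all(np.isfinite(h)):
            raise MetricsError("height map contains non-finite values")
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class FretMeasurement:
    """Donor lifetimes (ns) with and without acceptor, plus condition metadata."""

    tau_donor_only: float
    tau_donor_acceptor: float
    delta_osm: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_donor_only <= 0 or self.tau_donor_acceptor <= 0:
            raise MetricsError("lifetimes must be > 0")
        if self.tau_donor_acceptor > self.tau_donor_only:
            warnings.warn(
                "tau_DA > tau_D: negative apparent FRET efficiency",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NanobarGeometry:
    """Nanobar footprint: a rectangle capped by two half-discs.

    ``length`` is the full tip-to-tip extent (default 2000 nm) including
    the 125-nm-radius end caps; ``center`` and ``angle`` place the bar in
    the image (pixel coordinates, degrees counter-clockwise from the
    x-axis); ``pixel_size`` is nm per pixel.
    """

    length: float = 2000.0
    width: float = 250.0
    center: tuple = (0.0, 0.0)
    angle: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.length > self.width > 0:
            raise MetricsError("nanobar needs length > width > 0")
        if self.pixel_size <= 0:
            raise MetricsError("pixel_size must be > 0")

    @property
    def end_radius(self) -> float:
        return self.width / 2.0


@dataclass(frozen=True)
class SPRRecord:
    """One steady-state SPR reading: protein response over lipid deposition."""

    ru_solute: float
    ru_lipid: float
    concentration: float
    vesicle_diameter: float

    def __post_init__(self) -> None:
        if self.ru_lipid <= 0:
            raise MetricsError("RU_L (lipid deposition response) must be > 0")
        if self.concentration < 0:
            raise MetricsError("concentration must be >= 0")


def rq_roughness(height_map: HeightMap, leveling: str = "mean") -> float:
    """RMS roughness R_q (nm): sqrt(mean squared height deviation).

    ``leveling='mean'`` subtracts the mean height; ``'plane'`` removes
    the best-fit plane first (tilt-invariant). A constant map returns 0.
    """
    h = height_map.heights
    if leveling == "mean":
        dev = h - h.mean()
    elif leveling == "plane":
        ny, nx = h.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        design = np.column_stack([np.ones(h.size), xx.ravel(), yy.ravel()])
        coef, *_ = np.linalg.lstsq(design, h.ravel(), rcond=None)
        dev = h - (design @ coef).reshape(h.shape)
    else:
        raise MetricsError(f"unknown leveling {leveling!r}")
    return float(np.sqrt(np.mean(dev**2)))


def fret_efficiency(measurement: FretMeasurement) -> float:
    """Lifetime FRET efficiency E = 1 - tau_DA / tau_D."""
    return 1.0 - measurement.tau_donor_acceptor / measurement.tau_donor_only


def nanobar_masks(shape: tuple, geometry: NanobarGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(end_mask, center_mask) boolean pixel masks for a nanobar image.

    End region: the two half-disc caps at the bar tips. Center region:
    the axial central rectangle whose area equals the combined cap area
    (half-length ``pi R^2 / (2 W)`` along the axis), so both means are
    taken over equal areas.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = geometry.center
    dx = (xx - cx) * geometry.pixel_size
    dy = (yy - cy) * geometry.pixel_size
    theta = math.radians(geometry.angle)
    u = dx * math.cos(theta) + dy * math.sin(theta)   # along the bar axis
    v = -dx * math.sin(theta) + dy * math.cos(theta)  # across the bar

    radius = geometry.end_radius
    half_body = geometry.length / 2.0 - radius  # cap centers at +/- half_body
    cap = (np.abs(u) >= half_body) & (
        (np.abs(u) - half_body) ** 2 + v**2 <= radius**2
    )
    center_half = math.pi * radius**2 / (2.0 * geometry.width)
    center = (np.abs(u) <= center_half) & (np.abs(v) <= radius)
    return cap, center


def nanobar_end_center_ratio(
    image: np.ndarray, geometry: NanobarGeometry
) -> tuple[float, dict]:
    """Mean end-cap intensity over mean center intensity for one nanobar.

    Expects a background-subtracted image with the bar fully inside the
    frame. Returns the ratio plus the per-region means.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise MetricsError("expected a single-plane 2-D intensity image")
    end_mask, center_mask = nanobar_masks(image.shape, geometry)
    if not end_mask.any() or not center_mask.any():
        raise MetricsError("nanobar regions fall outside the image")
    end_mean = float(image[end_mask].mean())
    center_mean = float(image[center_mask].mean())
    if center_mean <= 0:
        raise MetricsError("undefined ratio: mean center intensity <= 0")
    return end_mean / center_mean, {"end_mean": end_mean, "center_mean": center_mean}


def nanobar_heatmap(images) -> np.ndarray:
    """Pixelwise mean of aligned nanobar sub-images (canonical orientation)."""
    stack = [np.asarray(im, dtype=float) for im in images]
    if len(stack) == 0:
        raise MetricsError("need at least one sub-image")
    shape = stack[0].shape
    if any(im.shape != shape for im in stack):
        raise MetricsError("sub-images must share one shape")
    return np.mean(stack, axis=0)


def subtract_background(image: np.ndarray, radius: int = 3) -> np.ndarray:
    """Rolling-ball-style background subtraction.

    The background is a grayscale morphological opening with a disc
    structuring element of the given pixel radius (the 2-D analogue of
    rolling a ball under the intensity surface); features smaller than
    the disc survive subtraction and flat backgrounds map to zero. The
    result is non-negative.
    """
    if radius < 1:
        raise MetricsError("radius must be >= 1 pixel")
    image = np.asarray(image, dtype=float)
    background = opening(image, disk(radius))
    return np.clip(image - background, 0.0, None)


def spr_binding_table(records) -> pd.DataFrame:
    """Assemble RU_S / RU_L binding isotherms from steady-state records.

    One row per record with the normalized response, sorted by
    concentration within each vesicle-diameter group.
    """
    records = list(records)
    if not records:
        raise MetricsError("no SPR records")
    frame = pd.DataFrame(
        {
            "vesicle_diameter": [rec.vesicle_diameter for rec in records],
            "concentration": [rec.concentration for rec in records],
            "ru_solute": [rec.ru_solute for rec in records],
            "ru_lipid": [rec.ru_lipid for rec in records],
        }
    )
    frame["ratio"] = frame["ru_solute"] / frame["ru_lipid"]
    frame = frame.sort_values(
        ["vesicle_diameter", "concentration"], kind="stable"
    ).reset_index(drop=True)
    return frame
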