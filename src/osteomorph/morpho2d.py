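"""Section-based (2D) morphometry of canal cross-sections and lacunae.

These estimators mirror the classical particle-analysis workflow on a single
binary section: fit the area-preserving second-moment ellipse to each
connected region, derive the longitudinal angle from the ellipse axis ratio
(``omega = arcsin(b / a)``), the radial angle from the major-axis direction
against the local bone-surface tangent, and lacunar volumes from one
(prolate-spheroid) or two (triaxial) perpendicular sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .phantoms import fold_axis_angle

__all__ = [
    "Region2D",
    "Ellipse2D",
    "LacunarVolumeEstimate",
    "DegenerateRegionError",
    "label_regions_2d",
    "fit_ellipse_moments",
    "omega_from_ellipse",
    "theta_from_ellipse",
    "separate_by_area_2d",
    "mean_volume_xy",
    "mean_volume_xy_xz",
    "AREA_CUTOFF_UM2",
]

#: 2D area above which an object counts as a vascular canal rather than an
#: osteocyte lacuna (strict inequality), in square micrometres.
AREA_CUTOFF_UM2 = 38.0


class DegenerateRegionError(ValueError):
    """Region too small or collinear for a moment-ellipse fit."""


@dataclass
class Region2D:
    """A labelled 8-connected pixel region of a binary section."""

    label: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel indices
    area: int           # pixel count
    centroid: Tuple[float, float]  # (row, col)


@dataclass
class Ellipse2D:
    """Area-preserving moment ellipse of a pixel region.

    ``a`` and ``b`` are the full major and minor axis lengths; ``phi`` the
    major-axis direction in degrees against the x-axis, normalised to
    [0, 180).  Units follow ``pixel_size`` (pixels when 1.0).
    """

    a: float
    b: float
    phi: float
    centroid: Tuple[float, float]  # (x, y)
    area: float

    @property
    def aspect(self) -> float:
        return self.b / self.a


def label_regions_2d(image: np.ndarray, connectivity: int = 2) -> List[Region2D]:
    """8-connected components of a binary section (background excluded)."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    labels = measure.label(arr > 0, connectivity=connectivity)
    regions = []
    for rp in measure.regionprops(labels):
        regions.append(Region2D(
            label=rp.label,
            coords=rp.coords,
            area=int(rp.area),
            centroid=tuple(rp.centroid),
        ))
    return regions


def fit_ellipse_moments(region: Region2D, pixel_size: float = 1.0) -> Ellipse2D:
    """Fit the standard particle-analysis ellipse to a pixel region.

    The ellipse shares the region's centroid and normalised second central
    moments, with the axis lengths rescaled so the ellipse area equals the
    region's pixel area exactly (area-preserving convention):
    ``aspect = sqrt(lambda1 / lambda2)``, ``a = 2 sqrt(A * aspect / pi)``.
    """
    coords = region.coords
    if len(coords) < 3:
        raise DegenerateRegionError(
            f"region {region.label}: {len(coords)} pixels, need >= 3"
        )
    x = coords[:, 1].astype(float)
    y = coords[:, 0].astype(float)
    cov = np.cov(np.stack([x, y]), ddof=0)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam2 <= 1e-12:
        raise DegenerateRegionError(
            f"region {region.label}: collinear pixels, moment ellipse undefined"
        )
    aspect = np.sqrt(lam1 / lam2)
    area = len(coords) * pixel_size ** 2
    a = 2.0 * np.sqrt(area * aspect / np.pi)
    b = 2.0 * np.sqrt(area / (aspect * np.pi))
    vx, vy = evecs[0, 1], evecs[1, 1]  # major-axis eigenvector (x, y)
    phi = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    return Ellipse2D(
        a=float(a),
        b=float(b),
        phi=phi,
        centroid=(float(x.mean() * pixel_size), float(y.mean() * pixel_size)),
        area=float(area),
    )


def omega_from_ellipse(a: float, b: float) -> float:
    """Longitudinal angle from the section-ellipse axis ratio.

    A circular cross-section (b = a) implies a canal running parallel to the
    bone's long axis (omega = 90 deg); an infinitely elongated one a
    transverse canal (omega -> 0).
    """
    if not (a >= b > 0):
        raise ValueError(f"need a >= b > 0, got a={a}, b={b}")
    return float(np.degrees(np.arcsin(min(b / a, 1.0))))


def theta_from_ellipse(phi: float, tangent_direction: float = 0.0) -> float:
    """Radial angle: acute angle between the section-ellipse major axis and
    the bone-surface tangent (the x-axis for phantoms), in [0, 90]."""
    if not (np.isfinite(phi) and np.isfinite(tangent_direction)):
        raise ValueError("angles must be finite")
    return fold_axis_angle(phi, tangent_direction)


def separate_by_area_2d(
    regions: Sequence[Region2D],
    pixel_area: float,
    cutoff: float = AREA_CUTOFF_UM2,
) -> Tuple[List[Region2D], List[Region2D]]:
    """Split 2D regions into (lacunae, canals) by physical area.

    Objects strictly larger than ``cutoff`` (38 um^2) are canals; everything
    else, including an object of exactly 38 um^2, is a lacuna.
    """
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    lacunae, canals = [], []
    for r in regions:
        (canals if r.area * pixel_area > cutoff else lacunae).append(r)
    return lacunae, canals


@dataclass
class LacunarVolumeEstimate:
    """Cohort mean lacunar volume (Lc.V-bar) from one of the three methods."""

    method: str  # xy_plane | xy_xz_plane | ellipsoid_3d
    mean_volume: float
    sd: float
    n: int
    volumes: np.ndarray
    n_skipped: int = 0


def _summarise(method: str, volumes: List[float], n_skipped: int) -> LacunarVolumeEstimate:
    if not volumes:
        raise ValueError(f"{method}: no objects to average")
    v = np.asarray(volumes, dtype=float)
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return LacunarVolumeEstimate(
        method=method,
        mean_volume=float(v.mean()),
        sd=sd,
        n=len(v),
        volumes=v,
        n_skipped=n_skipped,
    )


def mean_volume_xy(ellipses: Sequence[Ellipse2D]) -> LacunarVolumeEstimate:
    """Single-section prolate-spheroid estimate of mean lacunar volume.

    Each lacuna is modelled as a prolate spheroid whose major and minor radii
    are read off its transverse section ellipse: ``V = 4/3 pi r1 r2^2`` with
    ``r1 = a/2``, ``r2 = b/2`` (radii in micrometres).
    """
    vols = [4.0 / 3.0 * np.pi * (e.a / 2.0) * (e.b / 2.0) ** 2 for e in ellipses]
    return _summarise("xy_plane", vols, 0)


def mean_volume_xy_xz(
    xy_ellipses: Sequence[Optional[Ellipse2D]],
    xz_ellipses: Sequence[Optional[Ellipse2D]],
) -> LacunarVolumeEstimate:
    """Two-perpendicular-section triaxial estimate of mean lacunar volume.

    ``r2`` and ``r3`` come from the transverse (xy) section ellipse and
    ``r1`` from the major axis of the perpendicular (xz) section ellipse,
    assuming lacunae are on average aligned with the bone's long axis:
    ``V = 4/3 pi r1 r2 r3``.  Unpaired objects (a ``None`` in either list)
    are skipped and counted.
    """
    if len(xy_ellipses) != len(xz_ellipses):
        raise ValueError("xy and xz ellipse lists must be paired (equal length)")
    vols, skipped = [], 0
    for exy, exz in zip(xy_ellipses, xz_ellipses):
        if exy is None or exz is None:
            skipped += 1
            continue
        r1 = exz.a / 2.0
        r2 = exy.a / 2.0
        r3 = exy.b / 2.0
        vols.append(4.0 / 3.0 * np.pi * r1 * r2 * r3)
    return _summarise("xy_xz_plane", vols, skipped)
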