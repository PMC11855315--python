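"""Per-pore measurements: area, perimeter, IPR, ellipse fit, orientation.

Quantities
----------
area
    Either the shoelace area of the boundary polygon ("polygon" mode)
    or the number of lattice pixels inside-or-on the contour ("pixel"
    mode).  The two differ by about half the perimeter: the boundary
    polygon threads pixel *centers*, so it misses the half-pixel rim of
    the region.  The analysis pipeline uses pixel mode, which tracks
    the physical pore area; the polygon value is what the shoelace
    formula yields on the vertex list.
perimeter
    Sum of Euclidean edge lengths around the closed loop.
isoperimetric ratio (IPR)
    4π·area/perimeter² — 1 for a disc, smaller for elongated or
    irregular shapes; a disc-normalized compactness.
orientation
    From a direct least-squares ellipse fit to the boundary.  The
    orientation vector points along the major axis with magnitude
    major − minor (a circle has no orientation); pores carry no
    inherent direction, so angles are reported in [0°, 180°), measured
    from the +x axis with y increasing downward.
feret diameters
    Read from the fitted ellipse: minimum feret = minor axis length,
    maximum feret = major axis length.  A rotating-calipers mode on
    the polygon is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from skimage.measure import EllipseModel

from .errors import ContractError, FitImpossibleError, UndefinedIPRError
from .scale import ScaleSpec, convert_measurement

__all__ = [
    "EllipseFit",
    "PoreMeasurements",
    "polygon_area",
    "polygon_perimeter",
    "isoperimetric_ratio",
    "fit_ellipse",
    "orientation_vector",
    "pixels_within",
    "pixel_area",
    "centroid",
    "feret_diameters_calipers",
    "measure_pore",
]


def _vertices(contour) -> np.ndarray:
    v = np.asarray(getattr(contour, "vertices", contour), dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ContractError(f"expected (N, 2) vertex array, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse: center, full axis lengths, major-axis angle."""

    center: tuple[float, float]
    major_len: float
    minor_len: float
    angle_deg: float  # in [0, 180)


@dataclass(frozen=True)
class PoreMeasurements:
    """All reported quantities for one pore, in the scale's units."""

    area: float
    perimeter: float
    ipr: float
    centroid: tuple[float, float]
    orientation_angle_deg: float | None
    orientation_vector: tuple[float, float] | None
    feret_min: float | None
    feret_max: float | None
    units: str  # "px" or "um"


def polygon_area(contour) -> float:
    """Absolute shoelace area of the vertex polygon, in px².

    Orientation-independent; a 1- or 2-vertex contour has area 0.
    """
    v = _vertices(contour)
    if len(v) < 1:
        raise ContractError("contour has no vertices")
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def polygon_perimeter(contour) -> float:
    """Euclidean length of the closed boundary loop, in px.

    The closing edge from the last vertex back to the first is
    included, so a two-vertex "contour" traverses its segment twice.
    """
    v = _vertices(contour)
    if len(v) < 2:
        return 0.0
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def isoperimetric_ratio(area: float, perimeter: float) -> float:
    """IPR = 4πA/P²; equals 1 for a perfect disc."""
    if perimeter <= 0:
        raise UndefinedIPRError("perimeter must be > 0 to define the IPR")
    return 4.0 * math.pi * area / (perimeter * perimeter)


def fit_ellipse(contour) -> EllipseFit:
    """Direct least-squares ellipse fit to the contour vertices.

    Exact recovery when the vertices lie on an ellipse.  Requires at
    least 5 distinct points; fewer leave the conic underdetermined.
    """
    v = _vertices(contour)
    if len(np.unique(v, axis=0)) < 5:
        raise FitImpossibleError(
            f"ellipse fit needs >= 5 distinct points, got {len(np.unique(v, axis=0))}"
        )
    model = EllipseModel.from_estimate(v)
    if not model:
        raise FitImpossibleError(f"ellipse fit failed: {model}")
    a, b = model.axis_lengths  # semi-axes, major first
    angle = math.degrees(model.theta) % 180.0
    return EllipseFit(
        center=(float(model.center[0]), float(model.center[1])),
        major_len=2.0 * float(a),
        minor_len=2.0 * float(b),
        angle_deg=angle,
    )


def orientation_vector(fit: EllipseFit) -> tuple[tuple[float, float], float]:
    """Orientation vector and angle of a fitted ellipse.

    Magnitude is major − minor axis length (zero for a circle); the
    angle is normalized to [0, 180) — pores have no inherent
    direction, so all are taken to point rightward.
    Returns ``((vx, vy), angle_deg)``.
    """
    m = fit.major_len - fit.minor_len
    angle = fit.angle_deg % 180.0
    rad = math.radians(angle)
    return (m * math.cos(rad), m * math.sin(rad)), angle


def pixels_within(contour, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Lattice pixels inside or on the contour polygon, as an (M, 2) (x, y) array.

    The boundary vertices themselves are always included; interior
    lattice points are found by point-in-polygon testing.
    """
    v = _vertices(contour)
    iv = np.asarray(np.rint(v), dtype=np.int64)
    if len(iv) < 3:
        return np.unique(iv, axis=0)
    x0, y0 = iv.min(axis=0)
    x1, y1 = iv.max(axis=0)
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(v).contains_points(pts)
    combined = np.vstack([pts[inside], iv])
    pixels = np.unique(combined, axis=0)
    if shape is not None:
        h, w = shape
        keep = (
            (pixels[:, 0] >= 0) & (pixels[:, 0] < w) & (pixels[:, 1] >= 0) & (pixels[:, 1] < h)
        )
        pixels = pixels[keep]
    return pixels


def pixel_area(contour, shape: tuple[int, int] | None = None) -> float:
    """Number of lattice pixels inside or on the contour, in px²."""
    return float(len(pixels_within(contour, shape)))


def centroid(contour, binary: np.ndarray | None = None) -> tuple[float, float]:
    """Mean (x, y) of all pixels contained within the contour.

    Interior plus boundary pixels are averaged; a contour enclosing no
    interior falls back to the mean of its vertices.
    """
    shape = binary.shape if binary is not None else None
    px = pixels_within(contour, shape)
    if len(px) == 0:
        v = _vertices(contour)
        return (float(v[:, 0].mean()), float(v[:, 1].mean()))
    return (float(px[:, 0].mean()), float(px[:, 1].mean()))


def feret_diameters_calipers(contour) -> tuple[float, float]:
    """(min, max) feret diameters by rotating calipers on the convex hull.

    Alternative to reading the feret diameters off the fitted ellipse.
    """
    from scipy.spatial import ConvexHull

    v = _vertices(contour)
    pts = np.unique(v, axis=0)
    if len(pts) < 3:
        d = float(np.hypot(*(pts.max(axis=0) - pts.min(axis=0)))) if len(pts) else 0.0
        return d, d
    hull = pts[ConvexHull(pts).vertices]
    n = len(hull)
    edges = np.roll(hull, -1, axis=0) - hull
    angles = np.arctan2(edges[:, 1], edges[:, 0])
    fmax = 0.0
    fmin = math.inf
    for ang in angles:
        c, s = math.cos(-ang), math.sin(-ang)
        rot = hull @ np.array([[c, -s], [s, c]]).T
        w = rot[:, 1].max() - rot[:, 1].min()  # caliper width normal to this edge
        fmin = min(fmin, w)
    # max feret: largest pairwise distance over hull points
    diff = hull[:, None, :] - hull[None, :, :]
    fmax = float(np.sqrt((diff**2).sum(-1)).max())
    return float(fmin), fmax


def measure_pore(
    contour,
    binary: np.ndarray | None,
    scale: ScaleSpec,
    area_mode: str = "polygon",
    feret_mode: str = "ellipse",
) -> PoreMeasurements:
    """Assemble every reported quantity for one accepted contour.

    ``area_mode`` selects shoelace ("polygon") or enclosed-pixel-count
    ("pixel") area; ``feret_mode`` selects ellipse-axis ("ellipse") or
    rotating-calipers ("calipers") feret diameters.  Lengths and areas
    are converted through ``scale``; a failed ellipse fit (fewer than 5
    distinct boundary points) leaves the orientation and feret fields
    undefined rather than failing the pore.
    """
    if area_mode not in ("polygon", "pixel"):
        raise ContractError(f"unknown area_mode {area_mode!r}")
    if feret_mode not in ("ellipse", "calipers"):
        raise ContractError(f"unknown feret_mode {feret_mode!r}")
    shape = binary.shape if binary is not None else None
    area_px = polygon_area(contour) if area_mode == "polygon" else pixel_area(contour, shape)
    perim_px = polygon_perimeter(contour)
    ipr = isoperimetric_ratio(area_px, perim_px) if perim_px > 0 else float("nan")
    cx, cy = centroid(contour, binary)

    angle: float | None
    vec: tuple[float, float] | None
    feret_min_px: float | None
    feret_max_px: float | None
    try:
        fit = fit_ellipse(contour)
        vec, angle = orientation_vector(fit)
        if feret_mode == "ellipse":
            feret_min_px, feret_max_px = fit.minor_len, fit.major_len
        else:
            feret_min_px, feret_max_px = feret_diameters_calipers(contour)
    except FitImpossibleError:
        angle = vec = feret_min_px = feret_max_px = None

    f = scale.um_per_px if scale.mode == "supplied" else 1.0
    return PoreMeasurements(
        area=convert_measurement(area_px, "area", scale),
        perimeter=convert_measurement(perim_px, "length", scale),
        ipr=ipr,
        centroid=(cx, cy),
        orientation_angle_deg=angle,
        orientation_vector=None if vec is None else (vec[0] * f, vec[1] * f),
        feret_min=None if feret_min_px is None else feret_min_px * f,
        feret_max=None if feret_max_px is None else feret_max_px * f,
        units=scale.units,
    )
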