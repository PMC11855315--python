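"""Synthetic SEM-like phantom images with exhaustive ground truth.

A phantom emulates an SEM micrograph of a porous cryogel cross-section:
dark filled ellipses (pores — darkness encodes depth) on a lighter
matrix, an optional smooth linear illumination gradient, additive
Gaussian noise, and an optional information band with a drawn scalebar
along the bottom edge.  Every planted pore's center, semi-axes, angle
and analytic area/perimeter are returned, so detection and measurement
can be scored end-to-end without any external data.

What the phantom does *not* emulate: charging artifacts, depth of
field, partially merged pores, rough pore walls.  Recovery scores on
phantoms therefore bound digitization and pipeline error, not the full
difficulty of real micrographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import ContractError, InfeasibleSpecError

__all__ = [
    "PhantomSpec",
    "GroundTruthPore",
    "generate_phantom",
    "score_recovery",
    "RecoveryReport",
    "ground_truth_csv",
]


def _ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


@dataclass(frozen=True)
class GroundTruthPore:
    """One planted ellipse, in image coordinates (x = column, y = row)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float  # major-axis angle in [0, 180), y downward

    @property
    def true_area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor

    @property
    def true_perimeter(self) -> float:
        return _ramanujan_perimeter(self.semi_major, self.semi_minor)


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom image.

    Defaults are a 1024×1024 frame with 20 well-separated interior
    pores, semi-axes 10–40 px, dark pores (40) on a light matrix (200),
    no gradient and no noise — the clean baseline for recovery tests.
    ``illumination_gradient`` is the total left-to-right intensity
    swing in gray levels (±amplitude/2 about the mean).
    """

    width: int = 1024
    height: int = 1024
    n_pores: int = 20
    axis_range: tuple[float, float] = (10.0, 40.0)
    angle_distribution: str | float = "uniform"  # "uniform" or a fixed angle in degrees
    pore_intensity: int = 40
    background_intensity: int = 200
    illumination_gradient: float = 0.0
    noise_sigma: float = 0.0
    salt_pepper_fraction: float = 0.0
    min_gap: float = 8.0
    border_pore: bool = False  # additionally plant one pore crossing the border
    scalebar_band: tuple[int, int, float] | None = None  # (band height px, bar length px, reading µm)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pore_intensity < self.background_intensity <= 255):
            raise ContractError("need 0 <= pore_intensity < background_intensity <= 255")
        if self.axis_range[0] <= 0 or self.axis_range[0] > self.axis_range[1]:
            raise ContractError(f"bad axis_range {self.axis_range}")
        if self.n_pores < 0 or self.width < 1 or self.height < 1:
            raise ContractError("image dimensions must be positive and n_pores >= 0")

    def replace(self, **changes) -> "PhantomSpec":
        return replace(self, **changes)


def _place_pores(spec: PhantomSpec, rng: np.random.Generator) -> list[GroundTruthPore]:
    """Rejection-sample non-overlapping, fully interior pores."""
    lo, hi = spec.axis_range
    pores: list[GroundTruthPore] = []
    max_attempts = 2000 * max(spec.n_pores, 1)
    attempts = 0
    while len(pores) < spec.n_pores:
        if attempts >= max_attempts:
            raise InfeasibleSpecError(
                f"could not place {spec.n_pores} pores of semi-axes {spec.axis_range} "
                f"with min_gap {spec.min_gap} in a {spec.width}x{spec.height} frame"
            )
        attempts += 1
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, a)
        if spec.angle_distribution == "uniform":
            ang = rng.uniform(0.0, 180.0)
        else:
            ang = float(spec.angle_distribution) % 180.0
        margin = a + spec.min_gap
        if 2 * margin >= min(spec.width, spec.height):
            continue
        cx = rng.uniform(margin, spec.width - 1 - margin)
        cy = rng.uniform(margin, spec.height - 1 - margin)
        # conservative overlap check on bounding circles
        ok = all(
            math.hypot(cx - p.center[0], cy - p.center[1]) > a + p.semi_major + spec.min_gap
            for p in pores
        )
        if ok:
            pores.append(GroundTruthPore((cx, cy), a, b, ang))
    return pores


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, list[GroundTruthPore]]:
    """Render the phantom; deterministic given ``spec.seed``.

    Compositing order: flat background, illumination gradient, pores,
    Gaussian noise, salt-and-pepper noise, clip to [0, 255], then the
    optional scalebar band.  Returns the uint8 image and the ground
    truth (exactly ``n_pores`` rows; a border pore, when requested, is
    appended last and is *not* counted in ``n_pores``).
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), float(spec.background_intensity))
    if spec.illumination_gradient:
        ramp = np.linspace(
            -spec.illumination_gradient / 2.0, spec.illumination_gradient / 2.0, spec.width
        )
        img += ramp[None, :]

    pores = _place_pores(spec, rng)
    if spec.border_pore:
        a = (spec.axis_range[0] + spec.axis_range[1]) / 2.0
        pores = pores + [GroundTruthPore((0.0, spec.height / 2.0), a, a * 0.8, 0.0)]
    for p in pores:
        # skimage rotation is counter-clockwise in (row, col); with y
        # downward our angle convention maps to rotation = -angle
        rr, cc = draw_ellipse(
            p.center[1],
            p.center[0],
            p.semi_minor,
            p.semi_major,
            shape=img.shape,
            rotation=-math.radians(p.angle_deg),
        )
        img[rr, cc] = spec.pore_intensity

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.salt_pepper_fraction > 0:
        mask = rng.random(img.shape) < spec.salt_pepper_fraction
        img[mask] = np.where(rng.random(mask.sum()) < 0.5, 0.0, 255.0)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if spec.scalebar_band is not None:
        band_h, bar_px, _reading = spec.scalebar_band
        band_h = int(band_h)
        img[-band_h:, :] = 30
        y = spec.height - band_h // 2
        x0 = (spec.width - int(bar_px)) // 2
        img[y - 1 : y + 2, x0 : x0 + int(bar_px)] = 255
    return img, pores


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered the planted pores."""

    recall: float
    n_matched: int
    n_truth: int
    n_spurious: int
    mean_area_error: float  # mean |measured - true| / true over matches
    mean_angle_error_deg: float  # mod 180°, over matches with defined orientation
    per_pore: list[dict] = field(default_factory=list)


def _angle_diff(a: float, b: float) -> float:
    """Smallest difference between two undirected angles, in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def score_recovery(
    ground_truth: list[GroundTruthPore],
    accepted_records,
    match_radius: float | None = None,
    min_axis_difference: float = 2.0,
) -> RecoveryReport:
    """Match accepted pores to planted pores by nearest center.

    A record matches the nearest ground-truth pore whose center lies
    within ``match_radius`` (default: that pore's semi-minor axis).
    Unmatched records count as spurious; unmatched truths as misses.
    Area error is relative to the analytic πab; angle error is taken
    modulo 180° and skips pores whose fit left orientation undefined
    or whose planted semi-axis difference is below
    ``min_axis_difference`` (default 2 px, twice the half-pixel
    digitization scale of each boundary: a sub-pixel axis difference
    defines no orientation on the lattice — a circle has none at all).
    """
    unmatched = list(range(len(ground_truth)))
    matches: list[tuple[int, object]] = []
    n_spurious = 0
    for rec in accepted_records:
        cx, cy = rec.measurements.centroid
        best, best_d = None, math.inf
        for i in unmatched:
            gt = ground_truth[i]
            d = math.hypot(cx - gt.center[0], cy - gt.center[1])
            if d < best_d:
                best, best_d = i, d
        radius = (
            match_radius
            if match_radius is not None
            else (ground_truth[best].semi_minor if best is not None else 0.0)
        )
        if best is not None and best_d <= radius:
            unmatched.remove(best)
            matches.append((best, rec))
        else:
            n_spurious += 1

    area_errors, angle_errors, per_pore = [], [], []
    for i, rec in matches:
        gt = ground_truth[i]
        a_err = abs(rec.measurements.area - gt.true_area) / gt.true_area
        area_errors.append(a_err)
        entry = {"truth_index": i, "area_error": a_err, "angle_error": None}
        if (
            rec.measurements.orientation_angle_deg is not None
            and gt.semi_major - gt.semi_minor >= min_axis_difference
        ):
            ang_err = _angle_diff(rec.measurements.orientation_angle_deg, gt.angle_deg)
            angle_errors.append(ang_err)
            entry["angle_error"] = ang_err
        per_pore.append(entry)

    n_truth = len(ground_truth)
    return RecoveryReport(
        recall=len(matches) / n_truth if n_truth else 1.0,
        n_matched=len(matches),
        n_truth=n_truth,
        n_spurious=n_spurious,
        mean_area_error=float(np.mean(area_errors)) if area_errors else float("nan"),
        mean_angle_error_deg=float(np.mean(angle_errors)) if angle_errors else float("nan"),
        per_pore=per_pore,
    )


def ground_truth_csv(pores: list[GroundTruthPore]) -> str:
    """Serialize ground truth as CSV (one row per planted pore)."""
    lines = ["center_x,center_y,semi_major,semi_minor,angle_deg,true_area"]
    for p in pores:
        lines.append(
            f"{p.center[0]!r},{p.center[1]!r},{p.semi_major!r},{p.semi_minor!r},"
            f"{p.angle_deg!r},{p.true_area!r}"
        )
    return "\n".join(lines) + "\n"
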