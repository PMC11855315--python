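"""Reporting: summary statistics, CSV export, overlay rendering, image I/O.

The summary block mirrors what an interactive results box would show:
pore count, smallest/largest/mean/median pore area, its standard
deviation, mean perimeter, mean IPR and mean pore density.  Mean feret
diameters are computed but reported only in the CSV export.

The CSV schema is frozen: one row per pore, measurement columns first,
then the pore's save profile (the analysis settings of its pass), so
every exported pore documents exactly how it was obtained.

Overlay color semantics: detected contours green, saved gold, removed
by the size gate blue, removed by the hierarchy/border rule magenta,
removed by the user orange; numeric labels red.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import ContractError, EmptySummaryError, ExportError, FormatError, StateError
from .measurement import fit_ellipse
from .scale import ScaleSpec, convert_measurement
from .session import PoreRecord, Session

__all__ = [
    "SummaryStats",
    "DisplaySettings",
    "COLORS",
    "summarize",
    "session_records",
    "format_summary",
    "export_csv",
    "render_overlay",
    "save_png",
    "load_image",
]

logger = logging.getLogger("poremorph")

#: RGB overlay colors; "blue" is pure blue in RGB order.
COLORS = {
    "detected": (0, 255, 0),
    "saved": (255, 215, 0),
    "removed_size": (0, 0, 255),
    "removed_hierarchy": (255, 0, 255),
    "removed_user": (255, 165, 0),
    "label": (255, 0, 0),
}

CSV_COLUMNS = [
    "pass_id",
    "pore_id",
    "area",
    "perimeter",
    "ipr",
    "orientation_angle_deg",
    "orientation_vx",
    "orientation_vy",
    "center_x",
    "center_y",
    "feret_min",
    "feret_max",
    "units",
    "min_pore_size_px",
    "max_pore_size_px",
    "denoise_strength",
    "denoise_size",
    "grayscale_threshold",
    "clahe_size",
    "clahe_clip_limit",
    "scale_mode",
    "um_per_px",
]


@dataclass(frozen=True)
class SummaryStats:
    """Aggregate statistics over one pore list.

    Areas in µm² (px² in pixel mode), perimeter and feret diameters in
    µm (px), density in pores/mm² (None in pixel mode).  ``std_area``
    is the sample (n−1) standard deviation; for a single pore it is
    reported as 0 with ``degenerate_n`` set.
    """

    n_pores: int
    min_area: float
    max_area: float
    mean_area: float
    median_area: float
    std_area: float
    mean_perimeter: float
    mean_ipr: float
    mean_density: float | None
    mean_feret_min: float | None
    mean_feret_max: float | None
    units: str
    degenerate_n: bool = False


@dataclass(frozen=True)
class DisplaySettings:
    """What the overlay shows."""

    show_detected: bool = True
    show_saved: bool = True
    show_removed: bool = False
    show_numbers: bool = False
    orientation_mode: str = "none"  # none | orientation | major_axis | minor_axis | ellipse
    underlay: str = "original"  # original | clahe | denoised | threshold


def session_records(session: Session, which: str) -> list[PoreRecord]:
    """Select the detected or the saved pore list of a session."""
    if which == "detected":
        return list(session.current_detected)
    if which == "saved":
        return list(session.saved)
    raise ContractError(f"which must be 'detected' or 'saved', got {which!r}")


def summarize(
    records: list[PoreRecord],
    scale: ScaleSpec,
    image_dims: tuple[int, int],
) -> SummaryStats:
    """Summary statistics over a pore-record list.

    Density is the pore count over the full analyzed image area
    converted to mm² (the user supplies a cropped image, so the whole
    frame is the analyzed region); it is undefined in pixel mode.
    """
    if not records:
        raise EmptySummaryError("no pores to summarize")
    areas = np.array([r.measurements.area for r in records], dtype=float)
    perims = np.array([r.measurements.perimeter for r in records], dtype=float)
    iprs = np.array([r.measurements.ipr for r in records], dtype=float)
    ferets_min = [r.measurements.feret_min for r in records if r.measurements.feret_min is not None]
    ferets_max = [r.measurements.feret_max for r in records if r.measurements.feret_max is not None]
    n = len(records)
    degenerate = n < 2
    h, w = image_dims
    if scale.mode == "pixel":
        density = None
    else:
        density = convert_measurement(n / (h * w), "inverse_area", scale)
    return SummaryStats(
        n_pores=n,
        min_area=float(areas.min()),
        max_area=float(areas.max()),
        mean_area=float(areas.mean()),
        median_area=float(np.median(areas)),
        std_area=0.0 if degenerate else float(areas.std(ddof=1)),
        mean_perimeter=float(perims.mean()),
        mean_ipr=float(np.nanmean(iprs)),
        mean_density=density,
        mean_feret_min=float(np.mean(ferets_min)) if ferets_min else None,
        mean_feret_max=float(np.mean(ferets_max)) if ferets_max else None,
        units=scale.units,
        degenerate_n=degenerate,
    )


def format_summary(stats: SummaryStats) -> str:
    """Human-readable results block (what the CLI prints)."""
    u = stats.units
    lines = [
        f"pores:           {stats.n_pores}",
        f"smallest pore:   {stats.min_area:.2f} {u}^2",
        f"largest pore:    {stats.max_area:.2f} {u}^2",
        f"mean pore area:  {stats.mean_area:.2f} {u}^2",
        f"median pore area:{stats.median_area:.2f} {u}^2",
        f"std pore area:   {stats.std_area:.2f} {u}^2",
        f"mean perimeter:  {stats.mean_perimeter:.2f} {u}",
        f"mean IPR:        {stats.mean_ipr:.2f}",
    ]
    if stats.mean_density is not None:
        lines.append(f"mean density:    {stats.mean_density:.2f} pores/mm^2")
    return "\n".join(lines)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def export_csv(session: Session, which: str, path: str | Path | None = None) -> str:
    """Export one row per pore, with its save profile, as CSV text.

    Column order is frozen (see ``CSV_COLUMNS``); comma-delimited,
    '.' decimal point, UTF-8, LF line endings.  Returns the CSV text;
    writes it to ``path`` when given.
    """
    records = session_records(session, which)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for rec in records:
        m = rec.measurements
        p = rec.save_profile
        vx, vy = m.orientation_vector if m.orientation_vector is not None else (None, None)
        writer.writerow(
            [
                rec.pass_id,
                rec.pore_id,
                _fmt(m.area),
                _fmt(m.perimeter),
                _fmt(m.ipr),
                _fmt(m.orientation_angle_deg),
                _fmt(vx),
                _fmt(vy),
                _fmt(m.centroid[0]),
                _fmt(m.centroid[1]),
                _fmt(m.feret_min),
                _fmt(m.feret_max),
                m.units,
                _fmt(p.min_pore_size_px),
                _fmt(p.max_pore_size_px),
                _fmt(p.denoise_strength),
                p.denoise_size,
                p.grayscale_threshold,
                p.clahe_size,
                _fmt(p.clahe_clip_limit),
                p.scale.mode,
                _fmt(float(p.scale.um_per_px)),
            ]
        )
    text = buf.getvalue()
    if path is not None:
        try:
            Path(path).write_text(text, encoding="utf-8", newline="")
        except OSError as exc:
            raise ExportError(f"could not write CSV to {path}: {exc}") from exc
    return text


# -- overlay rendering --------------------------------------------------


def _draw_contour(rgb: np.ndarray, contour, color: tuple[int, int, int]) -> None:
    v = contour.vertices
    h, w = rgb.shape[:2]
    xs = np.clip(v[:, 0], 0, w - 1)
    ys = np.clip(v[:, 1], 0, h - 1)
    rgb[ys, xs] = color


def _draw_segment(rgb, x0, y0, x1, y1, color) -> None:
    from skimage.draw import line

    h, w = rgb.shape[:2]
    rr, cc = line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rgb[rr[keep], cc[keep]] = color


def _draw_orientation(rgb, rec: PoreRecord, mode: str, color) -> None:
    try:
        fit = fit_ellipse(rec.contour)
    except Exception:
        return
    cx, cy = fit.center
    if mode == "ellipse":
        from skimage.draw import ellipse_perimeter

        h, w = rgb.shape[:2]
        rr, cc = ellipse_perimeter(
            int(round(cy)),
            int(round(cx)),
            int(round(fit.minor_len / 2)),
            int(round(fit.major_len / 2)),
            orientation=-math.radians(fit.angle_deg),
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rgb[rr[keep], cc[keep]] = color
        return
    rad = math.radians(fit.angle_deg)
    if mode == "orientation":
        half = (fit.major_len - fit.minor_len) / 2.0
    elif mode == "major_axis":
        half = fit.major_len / 2.0
    elif mode == "minor_axis":
        half = fit.minor_len / 2.0
        rad += math.pi / 2.0
    else:
        raise ContractError(f"unknown orientation mode {mode!r}")
    dx, dy = half * math.cos(rad), half * math.sin(rad)
    _draw_segment(rgb, cx - dx, cy - dy, cx + dx, cy + dy, color)


def render_overlay(session: Session, display: DisplaySettings) -> np.ndarray:
    """Render the session over the chosen underlay as an (H, W, 3) RGB array.

    Pure function of the session and the display settings; the session
    is never modified.  Non-original underlays require at least one
    completed pass.
    """
    if display.underlay == "original":
        base = session.image
    else:
        if session.last_pass is None:
            raise StateError(f"underlay {display.underlay!r} requires a completed analysis pass")
        if display.underlay not in session.last_pass.stages:
            raise ContractError(f"unknown underlay {display.underlay!r}")
        base = session.last_pass.stages[display.underlay]
    rgb = np.stack([base] * 3, axis=-1).astype(np.uint8)

    last = session.last_pass
    if display.show_removed and last is not None:
        for c in last.detection.removed_size:
            _draw_contour(rgb, c, COLORS["removed_size"])
        for c in last.detection.removed_hierarchy:
            _draw_contour(rgb, c, COLORS["removed_hierarchy"])
        for rec in last.removed_user:
            _draw_contour(rgb, rec.contour, COLORS["removed_user"])
    if display.show_saved:
        for rec in session.saved:
            _draw_contour(rgb, rec.contour, COLORS["saved"])
    if display.show_detected:
        for rec in session.current_detected:
            _draw_contour(rgb, rec.contour, COLORS["detected"])
    if display.orientation_mode != "none":
        for rec in session.current_detected:
            _draw_orientation(rgb, rec, display.orientation_mode, COLORS["detected"])
        for rec in session.saved:
            _draw_orientation(rgb, rec, display.orientation_mode, COLORS["saved"])
    if display.show_numbers and session.current_detected:
        img = Image.fromarray(rgb)
        draw = ImageDraw.Draw(img)
        for rec in session.current_detected:
            cx, cy = rec.measurements.centroid
            draw.text((cx, cy), str(rec.pore_id), fill=COLORS["label"])
        rgb = np.asarray(img)
    return rgb


# -- image I/O ----------------------------------------------------------

_SUPPORTED = {".png", ".tif", ".tiff"}


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Lossless PNG write of a grayscale or RGB uint8 array."""
    try:
        Image.fromarray(np.asarray(image, dtype=np.uint8)).save(str(path), format="PNG")
    except OSError as exc:
        raise ExportError(f"could not write PNG to {path}: {exc}") from exc


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG or TIFF as an 8-bit grayscale array.

    Color images are converted by ITU-R BT.601 luminance; 16-bit
    inputs are rescaled to 8-bit by a linear min–max mapping (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise FormatError(f"unsupported image format {path.suffix!r} (PNG or TIFF expected)")
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # BT.601 luminance
        arr = arr[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    elif arr.dtype == np.uint16 or (arr.dtype.kind in "iu" and arr.max(initial=0) > 255):
        lo, hi = int(arr.min()), int(arr.max())
        logger.warning("rescaling %s-bit image %s to 8-bit via min-max [%d, %d]", arr.dtype, path, lo, hi)
        span = max(hi - lo, 1)
        arr = np.rint((arr.astype(float) - lo) / span * 255.0).astype(np.uint8)
    else:
        arr = arr.astype(np.uint8)
    return arr
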