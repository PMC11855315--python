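"""Scale handling and analysis settings.

An SEM micrograph carries an information band with a scalebar.  Users
measure the bar length in pixels and read its nominal length in
micrometers; the ratio converts every pixel measurement to physical
units.  In "pixel" mode no conversion is applied and all outputs stay
in px / px².

:class:`AnalysisSettings` bundles the six tunable parameters of one
analysis pass together with the scale; a frozen copy of it becomes the
"save profile" attached to every saved pore.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ContractError, InvalidScaleError

__all__ = [
    "ScaleSpec",
    "AnalysisSettings",
    "make_scale",
    "convert_measurement",
    "settings_from_mapping",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Pixel-to-micrometer conversion for one image.

    Attributes
    ----------
    mode : {"pixel", "supplied"}
        "pixel" keeps all quantities in pixel units; "supplied"
        converts using a user-measured scalebar.
    scalebar_length_px : float or None
        Length of the scalebar in pixels (supplied mode).
    scalebar_reading_um : float or None
        Nominal scalebar reading in micrometers (supplied mode).
    """

    mode: str
    scalebar_length_px: float | None = None
    scalebar_reading_um: float | None = None

    @property
    def um_per_px(self) -> float:
        """Micrometers per pixel (exactly 1, dimensionless, in pixel mode)."""
        if self.mode == "pixel":
            return 1.0
        return self.scalebar_reading_um / self.scalebar_length_px

    @property
    def units(self) -> str:
        """Unit tag written into reports: "um" or "px"."""
        return "px" if self.mode == "pixel" else "um"


def make_scale(
    mode: str,
    scalebar_length_px: float | None = None,
    scalebar_reading_um: float | None = None,
) -> ScaleSpec:
    """Build a :class:`ScaleSpec`.

    Parameters
    ----------
    mode : {"pixel", "supplied"}
    scalebar_length_px, scalebar_reading_um :
        Required and strictly positive in supplied mode; ignored in
        pixel mode.

    Raises
    ------
    InvalidScaleError
        If mode is unknown, or a supplied-mode field is missing or
        non-positive.
    """
    if mode == "pixel":
        return ScaleSpec(mode="pixel")
    if mode != "supplied":
        raise InvalidScaleError(f"unknown scale mode {mode!r}")
    if scalebar_length_px is None or scalebar_reading_um is None:
        raise InvalidScaleError("supplied mode needs both scalebar length and reading")
    if not (scalebar_length_px > 0) or not (scalebar_reading_um > 0):
        raise InvalidScaleError(
            f"scalebar length ({scalebar_length_px}) and reading "
            f"({scalebar_reading_um}) must both be positive"
        )
    return ScaleSpec(
        mode="supplied",
        scalebar_length_px=float(scalebar_length_px),
        scalebar_reading_um=float(scalebar_reading_um),
    )


#: quantity -> exponent of um_per_px applied to the value
_QUANTITIES = ("length", "area", "inverse_area")


def convert_measurement(value: float, quantity: str, scale: ScaleSpec) -> float:
    """Convert a pixel-unit measurement to physical units.

    length  -> µm           (value × f)
    area    -> µm²          (value × f²)
    inverse_area -> per mm² (value × (10³/f)²); the input is a count
                    per pixel², e.g. pore density.

    Pixel mode is the identity on every quantity.
    """
    if quantity not in _QUANTITIES:
        raise ContractError(f"unknown quantity {quantity!r}; expected one of {_QUANTITIES}")
    if not math.isfinite(value):
        raise ContractError(f"non-finite measurement {value!r}")
    if quantity in ("length", "area") and value < 0:
        raise ContractError(f"negative {quantity} {value!r}")
    if scale.mode == "pixel":
        return float(value)
    f = scale.um_per_px
    if quantity == "length":
        return value * f
    if quantity == "area":
        return value * f * f
    # per px² -> per mm²: 1 px² = (f µm)² = f²·1e-6 mm²
    return value * 1e6 / (f * f)


@dataclass(frozen=True)
class AnalysisSettings:
    """All tunable parameters of one analysis pass (the save profile).

    Size gates compare contour *area* in pixels².  ``clahe_size`` is by
    default the tile-grid dimension (N gives an N×N tile grid);
    set ``clahe_mode="pixels"`` to interpret it as the tile side in
    pixels instead.
    """

    min_pore_size_px: float = 100.0
    max_pore_size_px: float = 1e6
    denoise_strength: float = 30.0
    denoise_size: int = 7
    grayscale_threshold: int = 100
    clahe_size: int = 8
    clahe_clip_limit: float = 2.0
    clahe_mode: str = "tiles"  # "tiles" (N×N grid) or "pixels" (tile side)
    scale: ScaleSpec = field(default_factory=lambda: ScaleSpec(mode="pixel"))

    def __post_init__(self) -> None:
        if not self.min_pore_size_px < self.max_pore_size_px:
            raise ContractError(
                f"min_pore_size_px ({self.min_pore_size_px}) must be < "
                f"max_pore_size_px ({self.max_pore_size_px})"
            )
        if self.min_pore_size_px < 0:
            raise ContractError("min_pore_size_px must be >= 0")
        if self.denoise_size % 2 == 0 or self.denoise_size < 1:
            raise ContractError(f"denoise_size must be odd and positive, got {self.denoise_size}")
        if self.denoise_strength < 0:
            raise ContractError("denoise_strength must be >= 0")
        if not 0 <= self.grayscale_threshold <= 255:
            raise ContractError(
                f"grayscale_threshold must be in [0, 255], got {self.grayscale_threshold}"
            )
        if self.clahe_size < 1:
            raise ContractError("clahe_size must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ContractError("clahe_clip_limit must be > 0")
        if self.clahe_mode not in ("tiles", "pixels"):
            raise ContractError(f"clahe_mode must be 'tiles' or 'pixels', got {self.clahe_mode!r}")

    def replace(self, **changes) -> "AnalysisSettings":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)


# keys accepted by settings_from_mapping, mirroring the dataclass fields
_SETTING_KEYS = {
    "min_pore_size_px": float,
    "max_pore_size_px": float,
    "denoise_strength": float,
    "denoise_size": int,
    "grayscale_threshold": int,
    "clahe_size": int,
    "clahe_clip_limit": float,
    "clahe_mode": str,
}


def settings_from_mapping(mapping: Mapping[str, object], scale: ScaleSpec) -> AnalysisSettings:
    """Build settings from a key=value mapping (config file / CLI flags).

    Keys mirror the :class:`AnalysisSettings` field names exactly;
    unknown keys raise :class:`ContractError` so typos fail loudly.
    """
    kwargs: dict[str, object] = {}
    for key, raw in mapping.items():
        if key not in _SETTING_KEYS:
            raise ContractError(f"unknown analysis setting {key!r}")
        kwargs[key] = _SETTING_KEYS[key](raw)
    return AnalysisSettings(scale=scale, **kwargs)
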