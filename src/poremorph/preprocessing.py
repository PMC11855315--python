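"""Image preprocessing: CLAHE -> non-local-means denoising -> cutoff threshold.

SEM images of gel cross-sections are rarely evenly lit: darkness encodes
depth, so a tilted cross-section shades one side of the frame and a
single global threshold then treats identical pores differently.
Contrast-limited adaptive histogram equalization (CLAHE) equalizes each
tile of the image separately (with a clip limit so local contrast is not
over-boosted), flattening the illumination before thresholding.
Non-local-means denoising then removes grain and stray pixels that would
otherwise be traced as spurious contours, and a global cutoff produces
the binary image handed to contour detection.

The pipeline order is fixed: CLAHE, then denoise, then threshold.
"""

from __future__ import annotations

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.restoration import denoise_nl_means

from .errors import ContractError, DegenerateTileError

__all__ = ["apply_clahe", "denoise_nlm", "apply_threshold", "preprocess", "BLACK", "WHITE"]

#: binary image coding: black = pore candidate, white = matrix
BLACK = 0
WHITE = 255

#: fixed non-local-means search window side (pixels); only the patch
#: size is exposed as a user setting.
_NLM_SEARCH_WINDOW = 21


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ContractError(f"expected a non-empty 2-D grayscale array, got shape {img.shape}")
    return img


def apply_clahe(
    img: np.ndarray,
    clahe_size: int,
    clip_limit: float = 2.0,
    mode: str = "tiles",
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Parameters
    ----------
    img : (H, W) uint8 array
    clahe_size : int
        Tile-grid dimension (``mode="tiles"``: N gives an N×N grid) or
        tile side in pixels (``mode="pixels"``).
    clip_limit : float
        Histogram clip limit on the OpenCV-style scale, i.e. the
        maximum bin count expressed as ``clip_limit × tile_area / 256``.
        Larger values allow more local contrast; the excess above the
        clip is redistributed uniformly over the histogram.

    Returns
    -------
    (H, W) uint8 array, same shape as the input.
    """
    img = _check_gray(img)
    h, w = img.shape
    if clahe_size < 1:
        raise ContractError("clahe_size must be >= 1")
    if mode == "tiles":
        if clahe_size > min(h, w):
            raise DegenerateTileError(
                f"clahe_size {clahe_size} exceeds the shorter image side {min(h, w)}"
            )
        kernel = (max(h // clahe_size, 1), max(w // clahe_size, 1))
    elif mode == "pixels":
        if clahe_size > min(h, w):
            raise DegenerateTileError(
                f"tile side {clahe_size} px exceeds the shorter image side {min(h, w)}"
            )
        kernel = (clahe_size, clahe_size)
    else:
        raise ContractError(f"unknown CLAHE mode {mode!r}")

    if img.min() == img.max():
        # single-bin histogram: equalization maps every pixel to one value
        return img.astype(np.uint8).copy()

    # skimage normalizes the clip by tile pixel count; the OpenCV-style
    # limit normalizes by tile_area/256, hence the /256 mapping.
    out = equalize_adapthist(
        img.astype(np.uint8), kernel_size=kernel, clip_limit=min(clip_limit / 256.0, 1.0)
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def denoise_nlm(img: np.ndarray, strength: float, kernel_size: int) -> np.ndarray:
    """Fast non-local-means denoising.

    Each pixel is replaced by a weighted average of pixels whose
    surrounding patches look similar; weights decay exponentially with
    patch distance scaled by ``strength`` (the filter parameter h, on
    the 0–255 gray scale).  ``kernel_size`` is the odd patch side in
    pixels; the search window is fixed at 21 px.
    """
    img = _check_gray(img)
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ContractError(f"kernel_size must be odd and >= 3, got {kernel_size}")
    if strength < 0:
        raise ContractError("strength must be >= 0")
    if strength == 0:
        return img.astype(np.uint8).copy()
    out = denoise_nl_means(
        img.astype(np.float64),
        patch_size=kernel_size,
        patch_distance=(_NLM_SEARCH_WINDOW - 1) // 2,
        h=float(strength),
        fast_mode=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_threshold(img: np.ndarray, cutoff: int) -> np.ndarray:
    """Global cutoff thresholding to a binary image.

    Pixels strictly below ``cutoff`` become black (pore candidates),
    pixels at or above it become white.  Raising the cutoff grows the
    black set monotonically, which visually "erodes" pore edges.
    """
    img = _check_gray(img)
    if not 0 <= cutoff <= 255:
        raise ContractError(f"cutoff must be in [0, 255], got {cutoff}")
    return np.where(img < cutoff, BLACK, WHITE).astype(np.uint8)


def preprocess(img: np.ndarray, settings) -> dict[str, np.ndarray]:
    """Run the full preprocessing chain with one settings bundle.

    Returns a dict of every intermediate stage (keys ``"original"``,
    ``"clahe"``, ``"denoised"``, ``"threshold"``) so callers can render
    any stage as an underlay.
    """
    img = _check_gray(img).astype(np.uint8)
    cla = apply_clahe(img, settings.clahe_size, settings.clahe_clip_limit, settings.clahe_mode)
    den = denoise_nlm(cla, settings.denoise_strength, settings.denoise_size)
    binary = apply_threshold(den, settings.grayscale_threshold)
    return {"original": img, "clahe": cla, "denoised": den, "threshold": binary}
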