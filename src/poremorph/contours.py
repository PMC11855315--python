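"""Contour tracing with hierarchy, and acceptance/rejection of pores.

The binary image's black regions are the pore candidates.  Each
8-connected black region contributes one outer contour; each hole in a
region contributes an inner contour whose parent is the outer one, and
black islands inside holes recurse further down.  This reproduces the
border-following view of a binary image (every boundary loop between
black and white becomes one contour, with containment links), built
here from connected-component labeling plus Moore-neighbor boundary
following.

Rejection rules: contours that touch the image border or that are
nested inside another contour are rejected outright ("hierarchy"
rejections); surviving root contours are then gated on area in pixels²
("size" rejections).  Hierarchy/border rejection is applied before the
size gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label

from .errors import ContractError
from .measurement import polygon_area
from .preprocessing import BLACK
from .scale import AnalysisSettings

__all__ = ["Contour", "DetectionResult", "trace_contours", "filter_contours"]

# clockwise 8-neighbor ring starting due north, as (dr, dc)
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass(frozen=True)
class Contour:
    """One closed boundary loop.

    ``vertices`` is an (N, 2) integer array of (x, y) pixel coordinates
    (x = column, y = row, origin top-left), consecutive vertices
    8-adjacent, with the loop closing from the last vertex back to the
    first.  ``parent_id`` links a nested contour to its enclosing one.
    """

    id: int
    vertices: np.ndarray
    parent_id: int | None
    touches_border: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 1:
            raise ContractError(f"contour vertices must be (N>=1, 2), got shape {v.shape}")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class DetectionResult:
    """Partition of all traced contours for one pass."""

    accepted: list[Contour]
    removed_size: list[Contour]
    removed_hierarchy: list[Contour]
    source_settings: AnalysisSettings | None = None

    @property
    def all_contours(self) -> list[Contour]:
        return self.accepted + self.removed_size + self.removed_hierarchy


def _as_black_mask(binary: np.ndarray) -> np.ndarray:
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ContractError(f"binary image must be 2-D, got shape {binary.shape}")
    if binary.dtype == bool:
        return binary
    values = np.unique(binary)
    if not np.isin(values, (0, 255)).all():
        raise ContractError(
            f"image is not binary: found values {values[:10].tolist()} (expected only 0 and 255)"
        )
    return binary == BLACK


def _moore_trace(
    mask: np.ndarray, start: tuple[int, int], backtrack: tuple[int, int]
) -> list[tuple[int, int]]:
    """Follow one boundary loop of ``mask`` (True pixels).

    ``start`` must lie in the mask and ``backtrack`` must be an
    8-neighbor of it outside the mask (or outside the image); the pair
    selects which boundary loop of the region is traced.  Returns the
    ordered (row, col) boundary pixels.  Terminates when the start
    pixel is re-entered heading the same way (Jacob's criterion).
    """
    h, w = mask.shape

    def is_set(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    path: list[tuple[int, int]] = []
    cur, prev = start, backtrack
    first_state = None
    max_steps = 8 * int(mask.sum()) + 16
    for _ in range(max_steps):
        d0 = _RING.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            i = (d0 + k) % 8
            r, c = cur[0] + _RING[i][0], cur[1] + _RING[i][1]
            if is_set(r, c):
                j = (i - 1) % 8
                nxt = (r, c)
                new_prev = (cur[0] + _RING[j][0], cur[1] + _RING[j][1])
                break
        if nxt is None:  # isolated pixel: 1-vertex contour
            return [cur]
        if first_state is None:
            first_state = (cur, nxt)
        elif (cur, nxt) == first_state:
            return path
        path.append(cur)
        cur, prev = nxt, new_prev
    raise RuntimeError("boundary following failed to close; mask is inconsistent")


def _topmost_leftmost(region: np.ndarray) -> tuple[int, int]:
    rs, cs = np.nonzero(region)
    i = np.lexsort((cs, rs))[0]
    return int(rs[i]), int(cs[i])


def _make_contour(
    cid: int, rc_path: list[tuple[int, int]], parent_id: int | None, shape: tuple[int, int]
) -> Contour:
    arr = np.array([(c, r) for r, c in rc_path], dtype=np.int64)
    h, w = shape
    touches = bool(
        (arr[:, 0] == 0).any()
        or (arr[:, 1] == 0).any()
        or (arr[:, 0] == w - 1).any()
        or (arr[:, 1] == h - 1).any()
    )
    return Contour(id=cid, vertices=arr, parent_id=parent_id, touches_border=touches)


def trace_contours(binary: np.ndarray) -> list[Contour]:
    """Trace every black/white boundary loop with containment links.

    Returns one outer contour per 8-connected black region (black is
    pore, white background is 4-connected — the standard duality), one
    inner contour per hole, parented to the region's outer contour, and
    recursively the contours of islands inside holes.  Contour ids are
    assigned in discovery order.
    """
    mask = _as_black_mask(binary)
    shape = mask.shape
    out: list[Contour] = []

    def recurse(black: np.ndarray, parent_id: int | None) -> None:
        if not black.any():
            return
        labels, n = sk_label(black, connectivity=2, return_num=True)
        # labels are assigned in raster-scan order, so an enclosing
        # region is always seen before any region nested inside it;
        # nested ones are skipped here and handled by the recursion.
        consumed = np.zeros(black.shape, bool)
        for lab in range(1, n + 1):
            region = labels == lab
            start = _topmost_leftmost(region)
            if consumed[start]:
                continue
            outer_path = _moore_trace(region, start, (start[0] - 1, start[1]))
            outer_id = len(out)
            out.append(_make_contour(outer_id, outer_path, parent_id, shape))

            filled = ndi.binary_fill_holes(region)
            consumed |= filled
            holes = filled & ~black  # true white holes (islands excluded)
            if not holes.any():
                continue
            hlabels, hn = sk_label(holes, connectivity=1, return_num=True)
            for hl in range(1, hn + 1):
                hole = hlabels == hl
                hstart = _hole_trace_start(hole, region)
                inner_path = _moore_trace(region, hstart[0], hstart[1])
                hole_id = len(out)
                out.append(_make_contour(hole_id, inner_path, outer_id, shape))
                # black islands enclosed by this hole
                islands = black & ndi.binary_fill_holes(hole) & ~hole
                recurse(islands, hole_id)

    recurse(mask, None)
    return out


def _hole_trace_start(
    hole: np.ndarray, region: np.ndarray
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(start, backtrack) for tracing a region's inner boundary around a hole.

    Scans the hole pixels in raster order for one whose north neighbor
    belongs to the region; that neighbor starts the trace, entered from
    the hole pixel below it.
    """
    rs, cs = np.nonzero(hole)
    order = np.lexsort((cs, rs))
    for i in order:
        r, c = int(rs[i]), int(cs[i])
        if r > 0 and region[r - 1, c]:
            return (r - 1, c), (r, c)
    raise RuntimeError("hole has no region pixel on its northern boundary")


def filter_contours(
    contours: list[Contour],
    min_pore_size_px: float,
    max_pore_size_px: float,
    image_dims: tuple[int, int] | None = None,
    settings: AnalysisSettings | None = None,
) -> DetectionResult:
    """Partition traced contours into accepted / size- / hierarchy-rejected.

    Border-touching or nested (non-root) contours are hierarchy
    rejections; the remaining root contours are gated on shoelace area
    in pixels².  The three output lists are disjoint and jointly cover
    the input.
    """
    accepted: list[Contour] = []
    removed_size: list[Contour] = []
    removed_hier: list[Contour] = []
    for c in contours:
        if c.parent_id is not None or c.touches_border:
            removed_hier.append(c)
        else:
            area = polygon_area(c)
            if area < min_pore_size_px or area > max_pore_size_px:
                removed_size.append(c)
            else:
                accepted.append(c)
    return DetectionResult(
        accepted=accepted,
        removed_size=removed_size,
        removed_hierarchy=removed_hier,
        source_settings=settings,
    )
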