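"""Character-image standardization pipeline.

Raw glyph rasters (rendered from fonts or supplied as files) pass through
four stages before measurement:

1. ``raw`` — as rendered/loaded, on a 500×500 canvas.
2. ``trimmed`` — tight foreground bounding box.
3. ``resized`` — scaled by one per-script ratio so the script's largest
   glyph fits a 490×490 box, re-centered on the 500×500 canvas.  A single
   ratio per script preserves the within-script size variation.
4. ``skeleton-standardized`` — medial-axis thinning, pruning of short
   skeleton branches (artifacts of the medial-axis transform), then
   dilation with a square structuring element, giving every glyph a
   uniform ~5 px stroke thickness.

All images are binary masks with foreground = True.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.morphology import medial_axis, thin

CANVAS = 500
FIT_BOX = 490
DEFAULT_PRUNE_LEN = 35
DEFAULT_DILATION_RADIUS = 2
DEFAULT_POINT_SIZE = 60


class Stage(str, enum.Enum):
    RAW = "raw"
    TRIMMED = "trimmed"
    RESIZED = "resized"
    STANDARDIZED = "skeleton-standardized"


class BlankGlyphError(ValueError):
    pass


@dataclass(frozen=True)
class GlyphImage:
    """Binary raster of one character at a defined pipeline stage."""

    pixels: np.ndarray  # 2-D bool, foreground=True
    stage: Stage = Stage.RAW

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.stage in (Stage.RESIZED, Stage.STANDARDIZED) and self.pixels.shape != (
            CANVAS,
            CANVAS,
        ):
            raise ValueError(f"stage {self.stage.value} requires a {CANVAS}×{CANVAS} canvas")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_blank(self) -> bool:
        return not self.pixels.any()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_image(path: str | Path, stage: Stage = Stage.RAW, dark_foreground: bool = True) -> GlyphImage:
    """Load a PNG/PBM/PNM image and re-binarize it.

    Grayscale inputs are collapsed at 50% of their dynamic range; by default
    the darker side is the character (black-on-white convention).  PBM files
    follow their own convention (1 = black = foreground).
    """
    img = Image.open(path)
    if img.mode == "1":
        arr = np.asarray(img, dtype=bool)
        fg = ~arr if dark_foreground else arr  # PIL mode "1": True = white
    else:
        arr = np.asarray(img.convert("L"), dtype=float)
        lo, hi = arr.min(), arr.max()
        if lo == hi:
            fg = np.zeros(arr.shape, dtype=bool)
        else:
            mid = (lo + hi) / 2.0
            fg = arr < mid if dark_foreground else arr > mid
    return GlyphImage(pixels=fg, stage=stage)


def save_image(glyph: GlyphImage, path: str | Path) -> None:
    """Write the mask as black character on white background (PNG or PBM)."""
    arr = np.where(glyph.pixels, 0, 255).astype(np.uint8)
    img = Image.fromarray(arr, mode="L")
    path = Path(path)
    if path.suffix.lower() in (".pbm", ".pnm"):
        img = img.convert("1")
    img.save(path)


# ---------------------------------------------------------------------------
# Optional font rendering
# ---------------------------------------------------------------------------


def render_glyph(font_file: str | Path, codepoint: int, point_size: int = DEFAULT_POINT_SIZE) -> GlyphImage | None:
    """Render one codepoint onto the 500×500 canvas at the given point size.

    Returns None (a missing-symbol marker) when the font produces no ink
    for the codepoint.  Requires Pillow's FreeType support.
    """
    from PIL import ImageDraw, ImageFont

    if point_size <= 0:
        raise ValueError("point size must be positive")
    font = ImageFont.truetype(str(font_file), point_size)
    img = Image.new("L", (CANVAS, CANVAS), 255)
    draw = ImageDraw.Draw(img)
    ch = chr(codepoint)
    draw.text((CANVAS // 2, CANVAS // 2), ch, font=font, fill=0, anchor="mm")
    mask = np.asarray(img) < 128
    if not mask.any():
        return None
    return GlyphImage(pixels=mask, stage=Stage.RAW)


def render_script(font_file: str | Path, codepoints, initial_point_size: int = DEFAULT_POINT_SIZE):
    """Render a whole script, backing the point size off 5-by-5 on overflow.

    If any glyph of the script overflows the canvas (ink on the border
    row/column) the entire script is re-rendered at ``point_size - 5``,
    until every glyph fits.  Returns (dict codepoint -> GlyphImage | None,
    final point size).
    """
    size = initial_point_size
    while True:
        if size <= 0:
            raise ValueError("point size reached 0 before all glyphs fit the canvas")
        rendered: dict[int, GlyphImage | None] = {}
        overflow = False
        for cp in codepoints:
            g = render_glyph(font_file, cp, size)
            rendered[cp] = g
            if g is not None:
                px = g.pixels
                if px[0].any() or px[-1].any() or px[:, 0].any() or px[:, -1].any():
                    overflow = True
                    break
        if not overflow:
            return rendered, size
        size -= 5


# ---------------------------------------------------------------------------
# Standardization stages
# ---------------------------------------------------------------------------


def trim(glyph: GlyphImage) -> GlyphImage:
    """Crop to the tight foreground bounding box."""
    px = glyph.pixels
    if not px.any():
        raise BlankGlyphError("cannot trim a blank image")
    rows = np.flatnonzero(px.any(axis=1))
    cols = np.flatnonzero(px.any(axis=0))
    cropped = px[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return GlyphImage(pixels=cropped, stage=Stage.TRIMMED)


def script_resize_ratio(trimmed) -> float:
    """One ratio per script: 490 / (largest dimension of the largest glyph)."""
    glyphs = list(trimmed)
    if not glyphs:
        raise ValueError("need at least one trimmed image")
    largest = max(max(g.height, g.width) for g in glyphs)
    return FIT_BOX / largest


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def resize_and_center(glyph: GlyphImage, ratio: float) -> GlyphImage:
    """Scale by ``ratio`` (aspect preserved) and center on the 500×500 canvas.

    Target dimensions are rounded half away from zero and clamped to 490.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    h, w = glyph.height, glyph.width
    nh = min(FIT_BOX, max(1, _round_half_away(h * ratio)))
    nw = min(FIT_BOX, max(1, _round_half_away(w * ratio)))
    if _round_half_away(max(h, w) * ratio) > FIT_BOX:
        raise ValueError("ratio would scale the image beyond the 490×490 fit box")
    img = Image.fromarray(np.where(glyph.pixels, 255, 0).astype(np.uint8), mode="L")
    resized = np.asarray(img.resize((nw, nh), Image.BILINEAR)) >= 128
    canvas = np.zeros((CANVAS, CANVAS), dtype=bool)
    top = (CANVAS - nh) // 2
    left = (CANVAS - nw) // 2
    canvas[top : top + nh, left : left + nw] = resized
    return GlyphImage(pixels=canvas, stage=Stage.RESIZED)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def _walk_branch(skel: np.ndarray, start: tuple[int, int]):
    """Follow the skeleton from an endpoint until a junction or dead end.

    Returns (path pixels, Euclidean path length, reached_junction).
    """
    h, w = skel.shape
    path = [start]
    length = 0.0
    prev = None
    cur = start
    while True:
        r, c = cur
        nbrs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and skel[rr, cc] and (rr, cc) != prev:
                    nbrs.append((rr, cc))
        if prev is None:
            candidates = nbrs
        else:
            candidates = nbrs
        if not candidates:
            return path, length, False  # isolated path: whole component
        # junction test on the *next* pixel: count all its skeleton neighbors
        if len(candidates) > 1:
            # current pixel is itself a junction reached from the branch
            return path, length, True
        nxt = candidates[0]
        deg = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = nxt[0] + dr, nxt[1] + dc
                if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                    deg += 1
        step = np.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
        if deg >= 3:
            return path, length + step, True
        path.append(nxt)
        length += step
        prev, cur = cur, nxt


def prune_skeleton(skel: np.ndarray, min_length: float) -> np.ndarray:
    """Iteratively remove endpoint-to-junction branches shorter than
    ``min_length`` pixels (Euclidean path length).

    Whole components without a junction are kept regardless of length, so
    small genuine marks survive.  Repeats until stable, since removing a
    branch can expose new prunable branches.  Each sweep ends with a
    thinning pass that clears redundant pixels left where a removed branch
    attached diagonally to the remaining skeleton (thinning preserves
    topology and endpoints, so branch lengths are unaffected).
    """
    skel = thin(skel.astype(bool))
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        # evaluate every branch against the same snapshot, then remove all
        # prunable ones at once: sequential in-place removal would merge
        # sibling branches into the main path and make the result depend on
        # traversal order
        to_remove = []
        for r, c in endpoints:
            path, length, at_junction = _walk_branch(skel, (int(r), int(c)))
            if at_junction and length < min_length:
                to_remove.append(path)
        if to_remove:
            changed = True
            for path in to_remove:
                for rr, cc in path:
                    skel[rr, cc] = False
            skel = thin(skel)
    return skel


def skeleton_standardize(
    glyph: GlyphImage,
    prune_len: float = DEFAULT_PRUNE_LEN,
    dilation_radius: int = DEFAULT_DILATION_RADIUS,
) -> GlyphImage:
    """Thin to the medial axis, prune short branches, dilate to ~5 px strokes.

    The dilation uses a square structuring element of half-width
    ``dilation_radius``, so the output stroke thickness is
    2·dilation_radius + 1 pixels.
    """
    if glyph.stage is not Stage.RESIZED:
        raise ValueError("skeleton standardization expects a resized 500×500 image")
    if glyph.is_blank:
        raise BlankGlyphError("cannot standardize a blank image")
    skel = medial_axis(glyph.pixels, rng=0)  # fixed rng: deterministic tie-breaks
    pruned = prune_skeleton(skel, prune_len)
    if not pruned.any():
        raise BlankGlyphError(
            f"skeleton empty after pruning (prune_len={prune_len}); "
            "the glyph is smaller than the pruning threshold"
        )
    size = 2 * dilation_radius + 1
    dilated = ndimage.binary_dilation(pruned, structure=np.ones((size, size), bool))
    return GlyphImage(pixels=dilated, stage=Stage.STANDARDIZED)


def standardize_script(glyphs: dict, prune_len: float = DEFAULT_PRUNE_LEN, dilation_radius: int = DEFAULT_DILATION_RADIUS) -> dict:
    """Run trim → shared-ratio resize → skeleton standardization for one script.

    ``glyphs`` maps identifiers to raw GlyphImages; blank inputs are dropped
    (reported upstream as missing).
    """
    trimmed = {k: trim(g) for k, g in glyphs.items() if not g.is_blank}
    if not trimmed:
        return {}
    ratio = script_resize_ratio(trimmed.values())
    out = {}
    for k, t in trimmed.items():
        resized = resize_and_center(t, ratio)
        out[k] = skeleton_standardize(resized, prune_len, dilation_radius)
    return out
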