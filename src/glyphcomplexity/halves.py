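"""Vertical half-splitting and reading-order differentials.

Each standardized 500×500 glyph is cut into a left and a right 250×500
half.  Each half is padded with 50 background columns on its *inner* side
(the side where the cut ran) to 300×500, so that freshly created contours
do not sit on the image border, and both complexity metrics are measured on
the padded halves.

Differentials per character and metric:

* Δ_LR — left-half complexity minus right-half complexity;
* Δ_FL — first-half minus last-half complexity, where the *first* half is
  the one read first: left in a left-to-right script, right in a
  right-to-left one.  Hence Δ_FL = +Δ_LR for LR scripts and −Δ_LR for RL.
* D — discrepancy score of one half: z(PC) − z(AC), with z-scores taken
  over the whole population of analyzed halves.  D isolates where the two
  metrics disagree (e.g. a laterality bias specific to one metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complexity import BlankImageError, algorithmic_complexity, perimetric_complexity
from .corpus import Directionality
from .imaging import CANVAS, GlyphImage, Stage

HALF_WIDTH = 250
PADDED_WIDTH = 300
PAD_COLS = PADDED_WIDTH - HALF_WIDTH


def split_vertical(glyph: GlyphImage) -> tuple[np.ndarray, np.ndarray]:
    """Cut a 500-wide image into left (cols 0–249) and right (cols 250–499).

    No pixel is lost or duplicated; stacking the halves side by side
    reconstructs the input exactly.
    """
    px = glyph.pixels
    if px.shape[1] != CANVAS:
        raise ValueError(f"expected width {CANVAS}, got {px.shape[1]}")
    return px[:, :HALF_WIDTH].copy(), px[:, HALF_WIDTH:].copy()


def pad_inner(half: np.ndarray, which_side: str) -> np.ndarray:
    """Append 50 background columns on the cut ('inner') side.

    The left half is padded on its right edge, the right half on its left
    edge; output is exactly 300×500.
    """
    half = np.asarray(half, dtype=bool)
    if half.shape != (CANVAS, HALF_WIDTH):
        raise ValueError(f"expected a {CANVAS}×{HALF_WIDTH} half, got {half.shape}")
    pad = np.zeros((CANVAS, PAD_COLS), dtype=bool)
    if which_side == "left":
        return np.hstack([half, pad])
    if which_side == "right":
        return np.hstack([pad, half])
    raise ValueError("which_side must be 'left' or 'right'")


@dataclass
class HalfPair:
    """The two padded halves of one character plus their complexities.

    PC (field ``C_*``) is undefined (NaN) on a blank half; AC is always
    defined and equals the blank-canvas baseline there.
    """

    left: np.ndarray
    right: np.ndarray
    C_left: float
    C_right: float
    AC_left: int
    AC_right: int
    directionality: Directionality | None = None


def half_complexities(glyph: GlyphImage, directionality: Directionality | None = None) -> HalfPair:
    """Split, pad and measure both metrics on each half of one glyph."""
    if glyph.stage is not Stage.STANDARDIZED:
        raise ValueError("half-splitting expects a skeleton-standardized glyph")
    left_raw, right_raw = split_vertical(glyph)
    left = pad_inner(left_raw, "left")
    right = pad_inner(right_raw, "right")
    cs = []
    for h in (left, right):
        try:
            cs.append(perimetric_complexity(h).C)
        except BlankImageError:
            cs.append(float("nan"))
    return HalfPair(
        left=left,
        right=right,
        C_left=cs[0],
        C_right=cs[1],
        AC_left=algorithmic_complexity(left),
        AC_right=algorithmic_complexity(right),
        directionality=directionality,
    )


def left_right_differential(left_value: float, right_value: float) -> float:
    """Δ_LR: left-half complexity minus right-half complexity."""
    return left_value - right_value


def first_last_differential(
    left_value: float, right_value: float, directionality: Directionality
) -> float:
    """Δ_FL: first-half minus last-half complexity, by reading order."""
    if directionality is Directionality.LR:
        return left_value - right_value
    if directionality is Directionality.RL:
        return right_value - left_value
    raise ValueError(
        "first/last differential requires an LR or RL script "
        "(other directions are excluded upstream)"
    )


def discrepancy_scores(pc_values, ac_values) -> np.ndarray:
    """D = z(PC) − z(AC) per half, normalized over the pooled population.

    Both metrics are z-scored across all supplied halves (no grouping), so
    mean(D) = 0 by construction.  Requires nonzero variance in each metric.
    """
    pc = np.asarray(pc_values, dtype=float)
    ac = np.asarray(ac_values, dtype=float)
    if pc.shape != ac.shape or pc.ndim != 1 or len(pc) < 2:
        raise ValueError("need two 1-D arrays of equal length >= 2")
    out = np.full(len(pc), np.nan)
    ok = ~(np.isnan(pc) | np.isnan(ac))
    if ok.sum() < 2:
        raise ValueError("need at least 2 halves with both metrics")
    for arr in (pc, ac):
        if np.nanstd(arr[ok]) == 0:
            raise ValueError("zero variance in a metric; z-scores undefined")
    zpc = (pc[ok] - pc[ok].mean()) / pc[ok].std()
    zac = (ac[ok] - ac[ok].mean()) / ac[ok].std()
    out[ok] = zpc - zac
    return out


def build_half_table(glyphs, inventory) -> pd.DataFrame:
    """Measure halves for a whole corpus and assemble the tidy half table.

    Parameters
    ----------
    glyphs : mapping (script_code, codepoint) -> standardized GlyphImage
    inventory : list of ScriptRecord (provides directionality and family)

    Returns
    -------
    DataFrame with one row per half: script, family, type, codepoint, side
    (left/right), order (first/last, NaN for excluded directions), pc, ac,
    and per-character differentials d_lr_pc, d_lr_ac, d_fl_pc, d_fl_ac
    (repeated on both rows of a character).  The discrepancy score column
    ``d`` is z-normalized over all halves in the table with defined PC.
    """
    meta = {r.code: r for r in inventory}
    rows = []
    for (script, codepoint), glyph in glyphs.items():
        rec = meta.get(script)
        if rec is None:
            continue
        direction = rec.directionality
        pair = half_complexities(glyph, direction)
        d_lr_pc = left_right_differential(pair.C_left, pair.C_right)
        d_lr_ac = left_right_differential(pair.AC_left, pair.AC_right)
        if direction in (Directionality.LR, Directionality.RL):
            d_fl_pc = first_last_differential(pair.C_left, pair.C_right, direction)
            d_fl_ac = first_last_differential(pair.AC_left, pair.AC_right, direction)
            order_of = {"left": "first", "right": "last"} if direction is Directionality.LR else {
                "left": "last",
                "right": "first",
            }
        else:
            d_fl_pc = d_fl_ac = float("nan")
            order_of = {"left": None, "right": None}
        for side, pc, ac in (
            ("left", pair.C_left, pair.AC_left),
            ("right", pair.C_right, pair.AC_right),
        ):
            rows.append(
                {
                    "script": script,
                    "family": rec.family.value,
                    "type": rec.type.value,
                    "directionality": direction.value,
                    "codepoint": codepoint,
                    "side": side,
                    "order": order_of[side],
                    "pc": pc,
                    "ac": ac,
                    "d_lr_pc": d_lr_pc,
                    "d_lr_ac": d_lr_ac,
                    "d_fl_pc": d_fl_pc,
                    "d_fl_ac": d_fl_ac,
                }
            )
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        try:
            df["d"] = discrepancy_scores(df["pc"].to_numpy(), df["ac"].to_numpy())
        except ValueError:
            df["d"] = np.nan
    return df
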