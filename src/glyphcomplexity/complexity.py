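"""Visual complexity metrics for binary character images.

Two measures are provided.  Perimetric complexity C = P²/(4πA) relates the
total contour length P (inside and outside perimeters summed) to the inked
area A; it is dimensionless and minimized by a disk (C = 1).  Algorithmic
complexity AC is the byte size of a losslessly compressed canonical vector
rendering of the glyph outline — a practical proxy for description length.
Both operate on the binary foreground mask and are color-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from ._contours import compressed_vector_size, total_perimeter


class BlankImageError(ValueError):
    """Raised when a metric requiring foreground is applied to a blank image."""


@dataclass(frozen=True)
class ComplexityResult:
    """Per-image complexity measurements.

    Attributes
    ----------
    P : float
        Total sub-pixel contour length in pixels, summed over the outer
        outlines of all connected components and all hole outlines.
    A : float
        Foreground area in pixels².
    C : float
        Perimetric complexity P²/(4πA).
    AC : int or None
        Compressed vector byte count, if measured.
    """

    P: float
    A: float
    C: float
    AC: int | None = None


def perimetric_complexity(image: np.ndarray) -> ComplexityResult:
    """Measure perimetric complexity of a binary image.

    Parameters
    ----------
    image : ndarray of bool
        Foreground-true binary mask.

    Returns
    -------
    ComplexityResult with fields P, A and C populated.

    Raises
    ------
    BlankImageError
        If the image has no foreground pixels (C is undefined).
    """
    mask = np.asarray(image, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise BlankImageError("perimetric complexity is undefined on a blank image")
    perim = total_perimeter(mask)
    c = perim * perim / (4.0 * np.pi * area)
    return ComplexityResult(P=perim, A=area, C=c)


def algorithmic_complexity(image: np.ndarray) -> int:
    """Compressed byte count of the canonical vector form of the image.

    Blank images are legal and yield the baseline byte count (the header
    alone), the smallest value possible for the canvas.
    """
    return compressed_vector_size(np.asarray(image, dtype=bool))


def baseline_ac(shape: tuple[int, int] = (500, 500)) -> int:
    """AC of a blank canvas of the given shape."""
    return algorithmic_complexity(np.zeros(shape, dtype=bool))


def measure(image: np.ndarray, metrics: str = "pc,ac") -> ComplexityResult:
    """Measure the requested metrics ("pc", "ac" or "pc,ac") on one image."""
    wanted = {m.strip() for m in metrics.split(",")}
    unknown = wanted - {"pc", "ac"}
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    ac = algorithmic_complexity(image) if "ac" in wanted else None
    if "pc" in wanted:
        res = perimetric_complexity(image)
        return ComplexityResult(P=res.P, A=res.A, C=res.C, AC=ac)
    return ComplexityResult(P=np.nan, A=float(np.asarray(image).sum()), C=np.nan, AC=ac)


def metric_concordance(pc_values, ac_values) -> float:
    """Spearman rank correlation between the two complexity metrics.

    Requires at least three paired observations and nonzero variance in
    both metrics.
    """
    pc = np.asarray(pc_values, dtype=float)
    ac = np.asarray(ac_values, dtype=float)
    if pc.shape != ac.shape or pc.ndim != 1:
        raise ValueError("pc and ac must be 1-D arrays of equal length")
    if len(pc) < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(pc) == 0 or np.ptp(ac) == 0:
        raise ValueError("metric is constant; rank correlation undefined")
    rho = _sps.spearmanr(pc, ac).statistic
    return float(rho)
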