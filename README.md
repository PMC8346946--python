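# glyphcomplexity

Tools for studying the visual complexity of writing systems from character
images.  The package is aimed at researchers in cultural evolution and
visual cognition who want to ask questions like: do scripts with more
characters have more complex characters? how much of a character's
complexity is explained by the script, the script family, or the type of
writing system (alphabet, abjad, abugida, syllabary, logosyllabary,
featural)? do descendant scripts drift in complexity relative to their
ancestors? and is complexity distributed asymmetrically within characters
according to reading direction?

It provides the full measurement pipeline — image standardization, two
complexity metrics, reading-order half-splitting — plus the inferential
layer (random-intercept mixed models with ΔAIC comparison, variance
partitioning/ICC, a JZS Bayesian one-sample t-test) and a synthetic corpus
generator with known ground truth so every stage is testable without fonts
or downloads.

## The measures

**Perimetric complexity.** For a binary character image with total contour
length *P* (inside and outside perimeters summed) and inked area *A*,

    C = P² / (4πA)

*C* is dimensionless, scale-free, and minimized by a filled disk (*C* = 1).
Contours are traced at sub-pixel resolution with corner-preserving
smoothing, so the discretized estimate honors the analytic values (a disk
measures 1.000, a square 4/π ≈ 1.273).

**Algorithmic complexity.** The byte size of the losslessly compressed
canonical vector outline of the glyph — a practical proxy for description
length.  Deterministic and translation-invariant by construction; absolute
byte counts are comparable only within one implementation.

**Half differentials.** Standardized 500×500 glyphs are cut into 250×500
halves, padded on the inner side to 300×500, and measured per half.
Δ_LR = left − right; Δ_FL = first − last in reading order (so
Δ_FL = +Δ_LR in left-to-right scripts and −Δ_LR in right-to-left ones).
The discrepancy score D = z(PC) − z(AC) per half isolates metric-specific
laterality bias.

Before measurement every glyph is standardized: trimmed, resized with one
ratio per script (largest glyph fits 490×490, preserving within-script
size variation), re-centered on a 500×500 canvas, then thinned to its
medial axis, pruned of skeleton artifacts shorter than 35 px, and dilated
back to a uniform ~5 px stroke — so pen weight does not masquerade as
complexity.

## Worked example

```sh
python examples/measure_complexity.py
```

```
disk r=100    P=   628.3  A=   31428  C= 1.000  AC=2431 bytes
square 200    P=   798.1  A=   40000  C= 1.267  AC=1683 bytes
square+hole   P=  1036.2  A=   36400  C= 2.347  AC=2244 bytes
disk r=50 -> 0.997 | disk r=200 -> 1.0
```

The disk hits the theoretical minimum C = 1 and stays there across scales;
the square lands at 4/π; punching a hole adds contour while removing area,
raising C to the analytic (4·200+4·60)²/(4π·36400) ≈ 2.37.  The other
examples walk through standardization (`standardize_pipeline.py`), the
reading-order analyses (`half_differentials.py`) and variance/ancestry
inference (`variance_and_ancestry.py`).

A command-line pipeline wraps the same library for directory-level runs:

```sh
glyphcomplexity synth --out corpus --seed 1
glyphcomplexity run --corpus corpus --out results --skip-standardize
```

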