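"""Synthetic glyph corpora with known ground truth.

The generator emulates the *statistical* structure of a multi-script
character corpus — not typography.  Glyphs are random stroke arrangements
(line segments and curved strokes of ~5 px thickness, matching the output
of skeleton standardization) on the 500×500 canvas.  Complexity is driven
by stroke count, which follows a hierarchical log-normal design:

    log n_strokes = log(base) + type effect + script effect + character noise

with independent Gaussian effects whose standard deviations are the
controlled between-type / between-script / within-script variance knobs.
Left/right asymmetry is controlled by ``first_half_share``: each stroke is
placed entirely inside the half of the canvas read first (left for LR
scripts, right for RL) with that probability.  Ancestry: the first script
of each family is the family ancestor; its descendants inherit the script
effect shifted by the drift δ, so δ = 0 generates the null hypothesis of
no directional complexity change at branching events.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import CharacterRecord, Directionality, Family, ScriptRecord, ScriptType
from .imaging import CANVAS, GlyphImage, Stage, save_image

_MAX_STROKES = 60  # above this the canvas saturates and the draw is refused


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic corpus."""

    n_families: int = 4
    scripts_per_family: int = 5
    chars_per_script: int = 20
    base_strokes: float = 6.0
    type_effect_sd: float = 0.25      # between-type spread of log stroke count
    script_effect_sd: float = 0.15    # between-script spread within type
    char_noise_sd: float = 0.25       # within-script character noise
    p_lr: float = 0.78                # share of LR scripts (97/124 in real corpora)
    first_half_share: float = 0.5     # probability a stroke lands in the first half
    ancestry_drift: float = 0.0       # δ added to descendants' log stroke count
    canvas: int = CANVAS
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_families, self.scripts_per_family, self.chars_per_script) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.first_half_share <= 1.0:
            raise ValueError("first_half_share must lie in [0, 1]")
        if not 0.0 <= self.p_lr <= 1.0:
            raise ValueError("p_lr must lie in [0, 1]")
        if self.base_strokes < 1:
            raise ValueError("base_strokes must be >= 1")


@dataclass
class CorpusBundle:
    """In-memory synthetic corpus: inventory, characters, images, truth."""

    inventory: list[ScriptRecord]
    characters: list[CharacterRecord]
    glyphs: dict[tuple[str, str], GlyphImage]
    truth: dict = field(default_factory=dict)


def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(r, r, indexing="ij")
    keep = dr**2 + dc**2 <= radius**2 + 1
    return np.column_stack([dr[keep], dc[keep]])


_OFFSETS5 = _disk_offsets(2)  # ~5 px stroke thickness


def _stamp(mask: np.ndarray, points: np.ndarray) -> None:
    n = mask.shape[0]
    pts = np.round(points).astype(int)
    centers = pts[:, None, :] + _OFFSETS5[None, :, :]
    centers = centers.reshape(-1, 2)
    np.clip(centers, 0, n - 1, out=centers)
    mask[centers[:, 0], centers[:, 1]] = True


def _stroke_points(rng: np.random.Generator, row_lo, row_hi, col_lo, col_hi) -> np.ndarray:
    """Random straight or curved stroke inside the given box."""
    p0 = rng.uniform([row_lo, col_lo], [row_hi, col_hi])
    for _ in range(20):
        p1 = rng.uniform([row_lo, col_lo], [row_hi, col_hi])
        if np.hypot(*(p1 - p0)) >= 30:
            break
    t = np.linspace(0.0, 1.0, 120)[:, None]
    if rng.random() < 0.5:
        pts = p0 + t * (p1 - p0)
    else:
        mid = (p0 + p1) / 2 + rng.normal(0, 25, size=2)
        mid = np.clip(mid, [row_lo, col_lo], [row_hi, col_hi])
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * mid + t**2 * p1
    return pts


def generate_glyph(
    n_strokes: int,
    first_half_share: float = 0.5,
    directionality: Directionality = Directionality.LR,
    canvas: int = CANVAS,
    rng: np.random.Generator | int | None = None,
    stage: Stage = Stage.STANDARDIZED,
) -> GlyphImage:
    """Draw one synthetic glyph of ``n_strokes`` strokes.

    Each stroke is placed entirely inside the first-read half of the canvas
    with probability ``first_half_share`` and in the other half otherwise.
    Strokes are ~5 px thick, the thickness skeleton standardization
    produces, so synthetic glyphs can enter the pipeline at either stage.
    """
    if n_strokes < 1:
        raise ValueError("n_strokes must be >= 1")
    if n_strokes > _MAX_STROKES:
        raise ValueError(f"n_strokes={n_strokes} would saturate the canvas")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mask = np.zeros((canvas, canvas), dtype=bool)
    margin = 8
    mid = canvas // 2
    left_box = (margin, canvas - margin, margin, mid - 4)
    right_box = (margin, canvas - margin, mid + 4, canvas - margin)
    first_box, last_box = (
        (left_box, right_box) if directionality is Directionality.LR else (right_box, left_box)
    )
    for _ in range(n_strokes):
        box = first_box if rng.random() < first_half_share else last_box
        _stamp(mask, _stroke_points(rng, *box))
    return GlyphImage(pixels=mask, stage=stage)


_FAMILIES = list(Family)
_TYPES = list(ScriptType)


def generate_corpus(spec: GeneratorSpec, out_dir: str | Path | None = None) -> CorpusBundle:
    """Generate a full synthetic corpus (optionally written to disk).

    The first script of each family acts as the family's ancestor script;
    the remaining scripts of the family descend from it with their log
    stroke count shifted by ``ancestry_drift``.  Ground truth (realized
    effects, stroke counts and the generating parameters) is returned in
    ``truth`` and, when writing to disk, stored as ``truth.json`` alongside
    ``inventory.tsv``, ``characters.tsv`` and the PNG images.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    type_effects = {t.value: rng.normal(0.0, spec.type_effect_sd) for t in _TYPES}
    inventory: list[ScriptRecord] = []
    characters: list[CharacterRecord] = []
    glyphs: dict[tuple[str, str], GlyphImage] = {}
    truth_scripts: dict[str, dict] = {}

    script_index = 0
    for fam_i in range(spec.n_families):
        family = _FAMILIES[fam_i % len(_FAMILIES)]
        ancestor_code = None
        for s_i in range(spec.scripts_per_family):
            code = f"{chr(65 + fam_i % 26)}{script_index:03d}"
            script_index += 1
            stype = _TYPES[script_index % len(_TYPES)]
            direction = Directionality.LR if rng.random() < spec.p_lr else Directionality.RL
            script_eff = rng.normal(0.0, spec.script_effect_sd)
            drift = 0.0 if s_i == 0 else spec.ancestry_drift
            mean_log = (
                np.log(spec.base_strokes) + type_effects[stype.value] + script_eff + drift
            )
            stroke_counts = []
            for c_i in range(spec.chars_per_script):
                codepoint = f"{0x1000 + c_i:04X}"
                n_strokes = int(
                    np.clip(round(np.exp(mean_log + rng.normal(0.0, spec.char_noise_sd))), 1, _MAX_STROKES)
                )
                stroke_counts.append(n_strokes)
                glyph = generate_glyph(
                    n_strokes,
                    spec.first_half_share,
                    direction,
                    canvas=spec.canvas,
                    rng=rng,
                )
                glyphs[(code, codepoint)] = glyph
                characters.append(CharacterRecord(script_code=code, codepoint_id=codepoint))
            inventory.append(
                ScriptRecord(
                    code=code,
                    family=family,
                    type=stype,
                    directionality=direction,
                    inventory_size=spec.chars_per_script,
                    idiosyncratic=False,
                    ancestor=ancestor_code,
                    n_missing=0,
                )
            )
            truth_scripts[code] = {
                "family": family.value,
                "type": stype.value,
                "directionality": direction.value,
                "ancestor": ancestor_code,
                "script_effect": float(script_eff),
                "drift": float(drift),
                "mean_log_strokes": float(mean_log),
                "stroke_counts": stroke_counts,
            }
            if s_i == 0:
                ancestor_code = code

    truth = {
        "spec": asdict(spec),
        "type_effects": {k: float(v) for k, v in type_effects.items()},
        "scripts": truth_scripts,
    }
    bundle = CorpusBundle(inventory, characters, glyphs, truth)
    if out_dir is not None:
        _write_corpus(bundle, Path(out_dir))
    return bundle


def _write_corpus(bundle: CorpusBundle, out_dir: Path) -> None:
    from .corpus import write_inventory

    out_dir.mkdir(parents=True, exist_ok=True)
    write_inventory(bundle.inventory, out_dir / "inventory.tsv")
    with open(out_dir / "characters.tsv", "w") as fh:
        fh.write("script\tcodepoint\tinclude\n")
        for c in bundle.characters:
            fh.write(f"{c.script_code}\t{c.codepoint_id}\t1\n")
    img_dir = out_dir / "images"
    img_dir.mkdir(exist_ok=True)
    for (code, cp), glyph in bundle.glyphs.items():
        save_image(glyph, img_dir / f"{code}_{cp}.png")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
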