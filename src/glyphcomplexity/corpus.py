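"""Script/character inventory data model, I/O and inclusion rules.

A corpus consists of a script inventory table (one row per script, keyed by
its ISO 15924 code) and a companion character table (one row per character,
keyed by script code + codepoint identifier), with images stored one file
per character as ``<script>_<codepoint>.png``.

Inclusion rules implemented here:

* scripts with more than 5 missing symbols are excluded;
* character-level exclusions (punctuation, diacritics, numerals, ligatures)
  arrive as an upstream-curated boolean column, not a Unicode classifier;
* analyses of within-character order use only scripts whose dominant
  writing direction is left-to-right or right-to-left (vertical,
  boustrophedon, variable and uncertain directions are excluded).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

MAX_MISSING = 5  # scripts with up to this many missing symbols are kept


class Family(str, enum.Enum):
    MIDDLE_EASTERN = "MiddleEastern"
    PHOENICIAN = "Phoenician"
    INDIAN_BRAHMIC = "IndianBrahmic"
    MAINLAND_SEA = "MainlandSEA"
    INSULAR_SEA = "InsularSEA"
    RECENT_INVENTIONS = "RecentInventions"
    EAST_ASIAN = "EastAsian"


class ScriptType(str, enum.Enum):
    ALPHABET = "alphabet"
    ABJAD = "abjad"
    ABUGIDA = "abugida"
    SYLLABARY = "syllabary"
    LOGOSYLLABARY = "logosyllabary"
    FEATURAL = "featural"


class Directionality(str, enum.Enum):
    LR = "LR"
    RL = "RL"
    OTHER = "other"  # vertical, boustrophedon, variable or uncertain


@dataclass
class ScriptRecord:
    """Per-script metadata row."""

    code: str
    family: Family
    type: ScriptType
    directionality: Directionality
    inventory_size: int = 1
    idiosyncratic: bool = False
    ancestor: str | None = None
    n_missing: int = 0

    def __post_init__(self):
        if len(self.code) != 4:
            raise ValueError(f"ISO 15924 code must have 4 letters: {self.code!r}")
        if self.inventory_size < 1:
            raise ValueError("inventory_size must be >= 1")
        if self.ancestor == self.code:
            raise ValueError(f"script {self.code} cannot be its own ancestor")


@dataclass
class CharacterRecord:
    """One character of one script."""

    script_code: str
    codepoint_id: str
    image_path: Path | None = None
    include: bool = True


class SchemaError(ValueError):
    pass


class ValidationError(ValueError):
    pass


_REQUIRED_COLUMNS = ("code", "family", "type", "directionality")
_OPTIONAL_DEFAULTS = {
    "inventory_size": 1,
    "idiosyncratic": False,
    "ancestor": None,
    "n_missing": 0,
}


def _parse_enum(cls, value, default=None):
    try:
        return cls(value)
    except ValueError:
        if default is not None:
            return default
        raise


def load_inventory(path: str | Path, sep: str = "\t") -> list[ScriptRecord]:
    """Read a delimited-text script inventory into validated records.

    Unknown directionality values (e.g. vertical or boustrophedon labels)
    map to ``Directionality.OTHER``; unknown family/type values raise.
    Duplicate script codes raise a ValidationError.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"inventory file lacks required columns: {missing}")
    if df["code"].duplicated().any():
        dupes = sorted(df.loc[df["code"].duplicated(), "code"])
        raise ValidationError(f"duplicate script codes: {dupes}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, default in _OPTIONAL_DEFAULTS.items():
            if col in df.columns and row[col] != "":
                v = row[col]
                if col in ("inventory_size", "n_missing"):
                    v = int(v)
                elif col == "idiosyncratic":
                    v = v.strip().lower() in ("1", "true", "yes")
                kwargs[col] = v
            else:
                kwargs[col] = default
        records.append(
            ScriptRecord(
                code=row["code"],
                family=Family(row["family"]),
                type=ScriptType(row["type"]),
                directionality=_parse_enum(
                    Directionality, row["directionality"], Directionality.OTHER
                ),
                **kwargs,
            )
        )
    return records


def write_inventory(records, path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "code": r.code,
            "family": r.family.value,
            "type": r.type.value,
            "directionality": r.directionality.value,
            "inventory_size": r.inventory_size,
            "idiosyncratic": r.idiosyncratic,
            "ancestor": r.ancestor or "",
            "n_missing": r.n_missing,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_characters(path: str | Path, sep: str = "\t") -> list[CharacterRecord]:
    """Read the companion character table (script, codepoint, [include])."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("script", "codepoint"):
        if col not in df.columns:
            raise SchemaError(f"character file lacks required column: {col}")
    dup = df.duplicated(subset=["script", "codepoint"])
    if dup.any():
        raise ValidationError("duplicate (script, codepoint) pairs in character file")
    chars = []
    for _, row in df.iterrows():
        include = True
        if "include" in df.columns and row["include"] != "":
            include = row["include"].strip().lower() in ("1", "true", "yes")
        chars.append(
            CharacterRecord(
                script_code=row["script"], codepoint_id=row["codepoint"], include=include
            )
        )
    return chars


def inventory_size(characters) -> int:
    """Number of distinct codepoint identifiers among the given characters.

    Case variants carry distinct codepoints and therefore count separately
    (upper- and lower-case Latin letters give 52, not 26).
    """
    chars = [c for c in characters]
    if not chars:
        raise ValueError("cannot compute inventory size of an empty character list")
    return len({c.codepoint_id for c in chars})


@dataclass
class ExclusionLog:
    """Records why each excluded script was dropped."""

    excluded: dict[str, str] = field(default_factory=dict)

    def add(self, code: str, reason: str) -> None:
        self.excluded[code] = reason


def apply_script_inclusion(records, log: ExclusionLog | None = None) -> list[ScriptRecord]:
    """Keep scripts with at most 5 missing symbols.

    The filter is total (never raises) and idempotent.
    """
    kept = []
    for r in records:
        if r.n_missing > MAX_MISSING:
            if log is not None:
                log.add(r.code, f"{r.n_missing} missing symbols (> {MAX_MISSING})")
        else:
            kept.append(r)
    return kept


def order_analysis_subset(records, log: ExclusionLog | None = None) -> list[ScriptRecord]:
    """Keep only scripts written left-to-right or right-to-left.

    Scripts with vertical, boustrophedon, variable or uncertain dominant
    direction cannot enter first-half/last-half analyses.
    """
    kept = []
    for r in records:
        if r.directionality in (Directionality.LR, Directionality.RL):
            kept.append(r)
        elif log is not None:
            log.add(r.code, f"directionality {r.directionality.value}")
    return kept
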