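"""Anatomical model of the entorhinal/perirhinal cortex used throughout the package.

The entorhinal cortex (EC) is represented as ten scoring units derived from the
eight classical cytoarchitectonic subfields (EO, ER, ELr, EMI, EI, ELc, ECs, ECL),
with the intermediate (EI) and caudal (ECs) subfields bifurcated into medial and
lateral units because the medial-to-lateral burden gradient is scored separately
on each bank.  Two perirhinal units (Brodmann areas 35a and 35b) ride along in the
same machinery.  Coronal sampling positions are modelled as eight standardized
anterior-posterior (AP) levels anchored to amygdala/hippocampal landmarks; each
level carries the set of subfield units typically visible on a section cut there.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SubfieldUnit",
    "APLevel",
    "AgeGroup",
    "UNITS",
    "ENTORHINAL_UNITS",
    "PERIRHINAL_UNITS",
    "THICKNESS_UNITS",
    "LEVELS",
    "AGE_GROUPS",
    "subfields_at_level",
    "level_of_landmark",
    "age_group_of",
    "anatomy_table",
    "write_anatomy_csv",
    "load_anatomy_csv",
    "AnatomyError",
]

ANATOMY_TABLE_VERSION = "1.0"


class AnatomyError(ValueError):
    """Raised for out-of-range levels, unknown landmarks or malformed tables."""


@dataclass(frozen=True)
class SubfieldUnit:
    """One scoring unit of the medial temporal lobe parcellation."""

    code: str
    region_class: str  # "entorhinal" | "perirhinal"
    axis_position: str  # "anterior" | "intermediate" | "posterior"
    mediolateral: str  # "medial" | "lateral" | "unsplit"
    thickness_excluded: bool = False


@dataclass(frozen=True)
class APLevel:
    """One of the eight standardized coronal (anterior-posterior) levels."""

    index: int
    landmark: str
    expected_units: frozenset[str]
    optional_units: frozenset[str] = field(default_factory=frozenset)
    spacing_mm: float = 1.0  # minimum declared distance to the next level


@dataclass(frozen=True)
class AgeGroup:
    name: str
    lo: int
    hi: int | None  # None = open-ended


# --- unit catalogue -----------------------------------------------------------
# EMI is excluded from thickness measurements (the gyrus ambiens deforms in the
# sample tube during ex vivo scanning), hence the flag.

UNITS: dict[str, SubfieldUnit] = {
    u.code: u
    for u in [
        SubfieldUnit("EO", "entorhinal", "anterior", "unsplit"),
        SubfieldUnit("ER", "entorhinal", "anterior", "unsplit"),
        SubfieldUnit("ELr", "entorhinal", "anterior", "unsplit"),
        SubfieldUnit("EMI", "entorhinal", "intermediate", "medial", thickness_excluded=True),
        SubfieldUnit("EI_Med", "entorhinal", "intermediate", "medial"),
        SubfieldUnit("EI_Lat", "entorhinal", "intermediate", "lateral"),
        SubfieldUnit("ELc", "entorhinal", "intermediate", "unsplit"),
        SubfieldUnit("ECs_Med", "entorhinal", "posterior", "medial"),
        SubfieldUnit("ECs_Lat", "entorhinal", "posterior", "lateral"),
        SubfieldUnit("ECL", "entorhinal", "posterior", "unsplit"),
        SubfieldUnit("BA35a", "perirhinal", "intermediate", "unsplit"),
        SubfieldUnit("BA35b", "perirhinal", "intermediate", "unsplit"),
    ]
}

ENTORHINAL_UNITS: tuple[str, ...] = tuple(
    c for c, u in UNITS.items() if u.region_class == "entorhinal"
)
PERIRHINAL_UNITS: tuple[str, ...] = tuple(
    c for c, u in UNITS.items() if u.region_class == "perirhinal"
)
#: Units eligible for cortical-thickness sampling (EMI excluded).
THICKNESS_UNITS: tuple[str, ...] = tuple(
    c for c, u in UNITS.items() if u.region_class == "entorhinal" and not u.thickness_excluded
)

# --- AP level catalogue -------------------------------------------------------
# The published level table lists "EI" and "ECs" without the medial/lateral
# split; here they are expanded to both bank units because scores are collected
# per bank.  ECs is only sometimes still visible at level 7; it is carried as
# expected there but flagged optional.

LEVELS: dict[int, APLevel] = {
    lv.index: lv
    for lv in [
        APLevel(1, "anterior to the amygdala", frozenset({"EO"})),
        APLevel(2, "anterior amygdala", frozenset({"EO", "ER", "ELr"})),
        APLevel(3, "posterior amygdala", frozenset({"ELr", "EI_Med", "EI_Lat", "EMI"})),
        APLevel(4, "genu, hippocampal head", frozenset({"ELc", "EI_Med", "EI_Lat", "EMI"})),
        APLevel(5, "pes region, gyrus uncinatus", frozenset({"ECs_Med", "ECs_Lat"})),
        APLevel(6, "dentate gyrus and hippocampal head", frozenset({"ECs_Med", "ECs_Lat"})),
        APLevel(
            7,
            "posterior-most hippocampal head, gyrus intralimbicus",
            frozenset({"ECs_Med", "ECs_Lat", "ECL"}),
            optional_units=frozenset({"ECs_Med", "ECs_Lat"}),
        ),
        APLevel(8, "anterior hippocampal body", frozenset({"ECL"})),
    ]
}

#: Landmark aliases (lower-cased) -> level index.
_LANDMARK_ALIASES: dict[str, int] = {
    "anterior to the amygdala": 1,
    "anterior amygdala": 2,
    "posterior amygdala": 3,
    "genu, hippocampal head": 4,
    "genu": 4,
    "hippocampal head genu": 4,
    "pes region, gyrus uncinatus": 5,
    "pes region": 5,
    "gyrus uncinatus": 5,
    "dentate gyrus and hippocampal head": 6,
    "dentate gyrus": 6,
    "posterior-most hippocampal head, gyrus intralimbicus": 7,
    "gyrus intralimbicus": 7,
    "posterior-most hippocampal head": 7,
    "anterior hippocampal body": 8,
}

AGE_GROUPS: dict[str, AgeGroup] = {
    "youngest_old": AgeGroup("youngest_old", 59, 74),
    "middle_old": AgeGroup("middle_old", 75, 84),
    "oldest_old": AgeGroup("oldest_old", 85, None),
}


def subfields_at_level(
    level: int,
    *,
    include_perirhinal: bool = False,
    include_optional: bool = True,
) -> set[str]:
    """Unit codes expected on a section at AP level ``level`` (1-8).

    Perirhinal units BA35a/BA35b flank the EC along its whole extent and are
    scored at every level; they are appended when ``include_perirhinal`` is set.
    ``include_optional=False`` drops units that are only sometimes present at
    that level (ECs at level 7).
    """
    if level not in LEVELS:
        raise AnatomyError(f"AP level must be in 1..8, got {level!r}")
    lv = LEVELS[level]
    units = set(lv.expected_units)
    if not include_optional:
        units -= set(lv.optional_units)
    if include_perirhinal:
        units |= set(PERIRHINAL_UNITS)
    return units


def level_of_landmark(landmark_key: str) -> int:
    """Resolve an anatomical landmark description to its AP level index."""
    key = " ".join(landmark_key.strip().lower().split())
    try:
        return _LANDMARK_ALIASES[key]
    except KeyError:
        raise AnatomyError(f"unknown anatomical landmark: {landmark_key!r}") from None


def age_group_of(age: float) -> str:
    """Age-group name for an age in years.

    The cohort categories start at 59 y (youngest-old 59-74, middle-old 75-84,
    oldest-old >= 85).  Ages below 59 are mapped to ``youngest_old`` with a
    warning so the function stays total on valid ages.
    """
    if age < 0:
        raise AnatomyError(f"age must be nonnegative, got {age!r}")
    if age < AGE_GROUPS["youngest_old"].lo:
        warnings.warn(
            f"age {age} is below the youngest-old range (59-74); "
            "assigning youngest_old",
            stacklevel=2,
        )
        return "youngest_old"
    for g in AGE_GROUPS.values():
        if g.lo <= age and (g.hi is None or age <= g.hi):
            return g.name
    raise AnatomyError(f"age {age!r} not covered by any group")  # pragma: no cover


# --- table import/export ------------------------------------------------------


def anatomy_table() -> pd.DataFrame:
    """The level/landmark/unit table as a tidy DataFrame (one row per level)."""
    rows = []
    for lv in LEVELS.values():
        rows.append(
            {
                "level": lv.index,
                "landmark": lv.landmark,
                "units": ";".join(sorted(lv.expected_units)),
                "optional_units": ";".join(sorted(lv.optional_units)),
            }
        )
    df = pd.DataFrame(rows).sort_values("level").reset_index(drop=True)
    df.attrs["version"] = ANATOMY_TABLE_VERSION
    return df


def write_anatomy_csv(path) -> None:
    """Write the shipped anatomy table as a versioned CSV."""
    df = anatomy_table()
    with open(path, "w") as fh:
        fh.write(f"# ectau anatomy table v{ANATOMY_TABLE_VERSION}\n")
        df.to_csv(fh, index=False)


def load_anatomy_csv(path) -> dict[int, APLevel]:
    """Load an alternative level/unit table (same CSV layout) as APLevel records."""
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    df = pd.read_csv(io.StringIO("\n".join(lines)))
    required = {"level", "landmark", "units"}
    if not required.issubset(df.columns):
        raise AnatomyError(f"anatomy CSV must have columns {sorted(required)}")
    levels: dict[int, APLevel] = {}
    for _, row in df.iterrows():
        units = frozenset(str(row["units"]).split(";")) - {"", "nan"}
        opt = frozenset()
        if "optional_units" in df.columns and pd.notna(row.get("optional_units")):
            opt = frozenset(str(row["optional_units"]).split(";")) - {""}
        idx = int(row["level"])
        levels[idx] = APLevel(idx, str(row["landmark"]), units, opt)
    return levels
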