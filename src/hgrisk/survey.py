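"""Domain model and delimited-text I/O for a fish THg survey.

A survey is a tidy table with one row per specimen x organ: specimen
identity and morphometrics, the organ sampled, and the total-mercury
concentration in mg/kg wet weight.  Concentrations are held internally in
mg/kg ww without exception; microgram-per-kilogram input is accepted at the
I/O boundary only, via an explicit ``unit`` column, and converted on read.

The seven study species, their trophic guilds and the three cascade
reservoirs are first-class vocabulary here; unknown species are accepted if
a guild is supplied, so the model extends beyond the original survey.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .defaults import LOD_MG_KG

__all__ = [
    "ORGANS",
    "RESERVOIRS",
    "GUILDS",
    "SPECIES_TABLE",
    "Specimen",
    "TissueRecord",
    "Survey",
    "SurveyValidationError",
    "SurveySchemaError",
    "read_survey",
    "write_survey",
    "assign_size_classes",
]

#: Canonical organ tokens (nine organs are carried; the dissection protocol
#: lists seven, but heart and skin measurements occur in the summaries, so
#: the data model accepts all nine).
ORGANS: tuple[str, ...] = (
    "muscle",
    "liver",
    "kidneys",
    "spleen",
    "gills",
    "bones",
    "gonads",
    "hearts",
    "skin",
)

RESERVOIRS: tuple[str, ...] = ("kardzhali", "studen_kladenets", "ivaylovgrad")

GUILDS: tuple[str, ...] = ("predator", "omnivore")

SIZE_CLASSES: tuple[str, ...] = ("small", "large")

#: Study species -> (common name, trophic guild).
SPECIES_TABLE: dict[str, tuple[str, str]] = {
    "Cyprinus carpio": ("common carp", "omnivore"),
    "Squalius orpheus": ("orpheus dace", "omnivore"),
    "Vimba melanops": ("macedonian vimba", "omnivore"),
    "Silurus glanis": ("european catfish", "predator"),
    "Perca fluviatilis": ("european perch", "predator"),
    "Carassius gibelio": ("prussian carp", "omnivore"),
    "Rutilus rutilus": ("roach", "omnivore"),
}

#: Column order of the survey CSV schema.
CSV_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "species",
    "common_name",
    "guild",
    "reservoir",
    "tl_cm",
    "tw_g",
    "organ",
    "thg_mg_kg_ww",
    "below_lod",
)


class SurveySchemaError(ValueError):
    """The file does not have the expected columns/shape."""


class SurveyValidationError(ValueError):
    """One or more rows violate a survey invariant; message lists rows."""


@dataclass(frozen=True)
class Specimen:
    """One fish: identity, trophic guild, site and morphometrics."""

    specimen_id: str
    species: str
    common_name: str
    guild: str
    reservoir: str
    tl_cm: float
    tw_g: float
    size_class: str | None = None

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r}: unknown guild {self.guild!r}; "
                f"allowed: {GUILDS}"
            )
        if self.reservoir not in RESERVOIRS:
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r}: unknown reservoir "
                f"{self.reservoir!r}; allowed: {RESERVOIRS}"
            )
        if not (self.tl_cm > 0 and self.tw_g > 0):
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r}: TL and TW must be positive "
                f"(got TL={self.tl_cm}, TW={self.tw_g})"
            )
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r}: bad size class "
                f"{self.size_class!r}"
            )
        expected = SPECIES_TABLE.get(self.species)
        if expected is not None and expected[1] != self.guild:
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r}: {self.species} is a "
                f"{expected[1]}, not {self.guild!r}"
            )


@dataclass(frozen=True)
class TissueRecord:
    """One organ measurement: THg in mg/kg ww plus a below-LOD flag."""

    specimen_id: str
    organ: str
    thg_mg_kg_ww: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r}: unknown organ {self.organ!r}; "
                f"allowed: {ORGANS}"
            )
        if self.thg_mg_kg_ww < 0:
            raise SurveyValidationError(
                f"specimen {self.specimen_id!r} organ {self.organ}: negative "
                f"concentration {self.thg_mg_kg_ww}"
            )


@dataclass
class Survey:
    """A validated fish survey: specimens plus their tissue measurements."""

    specimens: list[Specimen] = field(default_factory=list)
    tissues: list[TissueRecord] = field(default_factory=list)
    lod_mg_kg: float = LOD_MG_KG

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SurveyValidationError(f"duplicate specimen ids: {dupes}")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        problems: list[str] = []
        for t in self.tissues:
            if t.specimen_id not in known:
                problems.append(
                    f"tissue record references unknown specimen "
                    f"{t.specimen_id!r}"
                )
            key = (t.specimen_id, t.organ)
            if key in seen:
                problems.append(f"duplicate record for {key}")
            seen.add(key)
            if t.below_lod and t.thg_mg_kg_ww > self.lod_mg_kg:
                problems.append(
                    f"{key}: flagged below LOD but {t.thg_mg_kg_ww} exceeds "
                    f"LOD {self.lod_mg_kg}"
                )
        if problems:
            raise SurveyValidationError("; ".join(problems))

    # -- convenience accessors -------------------------------------------

    def specimen(self, specimen_id: str) -> Specimen:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def species_list(self) -> list[str]:
        out: list[str] = []
        for s in self.specimens:
            if s.species not in out:
                out.append(s.species)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long tidy table, one row per specimen x organ (the CSV schema)."""
        spec = {s.specimen_id: s for s in self.specimens}
        rows = []
        for t in self.tissues:
            s = spec[t.specimen_id]
            rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "species": s.species,
                    "common_name": s.common_name,
                    "guild": s.guild,
                    "reservoir": s.reservoir,
                    "tl_cm": s.tl_cm,
                    "tw_g": s.tw_g,
                    "size_class": s.size_class,
                    "organ": t.organ,
                    "thg_mg_kg_ww": t.thg_mg_kg_ww,
                    "below_lod": t.below_lod,
                }
            )
        return pd.DataFrame(
            rows, columns=list(CSV_COLUMNS[:7]) + ["size_class", "organ",
                                                   "thg_mg_kg_ww", "below_lod"]
        )

    def muscle_values(self, species: str) -> np.ndarray:
        """Muscle THg values (mg/kg ww) for one species, survey order."""
        ids = [s.specimen_id for s in self.specimens if s.species == species]
        if not ids:
            raise KeyError(f"species {species!r} not in survey")
        by_id = {
            t.specimen_id: t.thg_mg_kg_ww
            for t in self.tissues
            if t.organ == "muscle"
        }
        return np.array([by_id[i] for i in ids if i in by_id], dtype=float)


def _canon_token(value: str, allowed: tuple[str, ...], what: str,
                 row: int) -> str:
    token = str(value).strip().lower().replace(" ", "_")
    if token not in allowed:
        raise SurveyValidationError(
            f"row {row}: unknown {what} {value!r}; allowed tokens: "
            f"{', '.join(allowed)}"
        )
    return token


def read_survey(path, *, lod_mg_kg: float = LOD_MG_KG,
                sep: str = ",") -> Survey:
    """Read a survey CSV into a validated :class:`Survey`.

    The expected schema is ``specimen_id, species, common_name, guild,
    reservoir, tl_cm, tw_g, organ, thg_mg_kg_ww, below_lod`` with one header
    row; an optional ``size_class`` column and an optional ``unit`` column
    (``mg_kg`` default, ``ug_kg`` converted by 1/1000) are honoured.  Rows
    violating invariants raise :class:`SurveyValidationError` naming the
    offending row (1-based data row index).
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = set(CSV_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise SurveySchemaError(
            f"missing required column(s): {sorted(missing)}"
        )

    specimens: dict[str, Specimen] = {}
    tissues: list[TissueRecord] = []
    for idx, rec in enumerate(df.to_dict("records"), start=1):
        organ = _canon_token(rec["organ"], ORGANS, "organ", idx)
        reservoir = _canon_token(rec["reservoir"], RESERVOIRS, "reservoir",
                                 idx)
        guild = _canon_token(rec["guild"], GUILDS, "guild", idx)
        conc = float(rec["thg_mg_kg_ww"])
        unit = str(rec.get("unit", "mg_kg") or "mg_kg").strip().lower()
        if unit in ("ug_kg", "µg_kg", "ug/kg"):
            conc /= 1000.0
        elif unit not in ("mg_kg", "mg/kg"):
            raise SurveySchemaError(f"row {idx}: unknown unit {unit!r}")
        size_class = rec.get("size_class")
        if size_class is not None and (pd.isna(size_class) or size_class == ""):
            size_class = None
        try:
            sp = Specimen(
                specimen_id=str(rec["specimen_id"]),
                species=str(rec["species"]),
                common_name=str(rec["common_name"]),
                guild=guild,
                reservoir=reservoir,
                tl_cm=float(rec["tl_cm"]),
                tw_g=float(rec["tw_g"]),
                size_class=size_class,
            )
            tissue = TissueRecord(
                specimen_id=str(rec["specimen_id"]),
                organ=organ,
                thg_mg_kg_ww=conc,
                below_lod=_parse_bool(rec["below_lod"]),
            )
        except SurveyValidationError as err:
            raise SurveyValidationError(f"row {idx}: {err}") from err
        prev = specimens.get(sp.specimen_id)
        if prev is not None and prev != sp:
            raise SurveyValidationError(
                f"row {idx}: specimen {sp.specimen_id!r} redefined with "
                f"conflicting attributes"
            )
        specimens[sp.specimen_id] = sp
        tissues.append(tissue)
    return Survey(list(specimens.values()), tissues, lod_mg_kg=lod_mg_kg)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def write_survey(survey: Survey, path) -> None:
    """Write a survey as CSV; ``read_survey`` round-trips it exactly."""
    df = survey.to_frame()
    if df.empty:
        df = pd.DataFrame(columns=list(CSV_COLUMNS[:7])
                          + ["size_class", "organ", "thg_mg_kg_ww",
                             "below_lod"])
    if isinstance(path, io.TextIOBase):
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False)


def assign_size_classes(survey: Survey, species: str,
                        reservoir: str | None = None) -> Survey:
    """Label a species' specimens small/large around the median total weight.

    Specimens strictly above the median TW become ``large``; the rest
    (including any specimen tied with the median) become ``small`` — the
    conservative direction for advisories, since smaller fish carry less
    mercury here.  With ``reservoir`` given, only that reservoir's specimens
    are classified (and the median is computed within it).
    """
    pool = [
        s for s in survey.specimens
        if s.species == species
        and (reservoir is None or s.reservoir == reservoir)
    ]
    if not pool:
        raise KeyError(
            f"species {species!r}"
            + (f" in reservoir {reservoir!r}" if reservoir else "")
            + " not present in survey"
        )
    if len(pool) < 2:
        raise SurveyValidationError(
            f"size classes need >= 2 specimens of {species!r}; got {len(pool)}"
        )
    median_tw = float(np.median([s.tw_g for s in pool]))
    selected = {s.specimen_id for s in pool}
    new_specimens = []
    for s in survey.specimens:
        if s.specimen_id in selected:
            label = "large" if s.tw_g > median_tw else "small"
            s = replace(s, size_class=label)
        new_specimens.append(s)
    return Survey(new_specimens, list(survey.tissues),
                  lod_mg_kg=survey.lod_mg_kg)
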