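"""Domain types, delimited-text I/O, validation, and deterministic derived quantities.

The analysis operates on three tidy CSV tables:

``fish.csv``
    one collected fish per row: identifiers, treatment, total length (cm),
    wet weight (kg), otolith age (yr), reproductive stage, fixed gonad
    weight (g), muscle %N, muscle d15N, collection day.
``transects.csv``
    long format, one observed fish per row; a row with blank species/length
    records a transect on which nothing was seen (a true zero).
``islands.csv``
    one island per row with named environmental covariates.

All readers accept a column-name mapping so externally formatted tables can
be ingested without editing the files.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Treatment",
    "Stage",
    "FishRecord",
    "TransectRecord",
    "IslandCovariates",
    "LengthWeightCoefficients",
    "SchemaError",
    "RowValidationError",
    "ConfigurationError",
    "compute_gsi",
    "length_to_weight",
    "transect_summaries",
    "read_fish_table",
    "write_fish_table",
    "read_transect_table",
    "write_transect_table",
    "read_island_table",
    "write_island_table",
    "read_length_weight_table",
    "write_length_weight_table",
]


class SchemaError(ValueError):
    """A required column is missing or a table is structurally malformed."""


class RowValidationError(ValueError):
    """One or more rows violate a record invariant; message carries row numbers."""


class ConfigurationError(ValueError):
    """User-supplied configuration is inconsistent with the data."""


class Treatment(str, enum.Enum):
    """Island treatment: presence/absence of invasive rats.

    Rat-free islands host dense breeding-seabird colonies whose guano
    subsidises the nearshore reef; rat-infested islands have near-zero
    seabird density. The labels stand in for high versus near-zero
    nutrient subsidy.
    """

    RAT_FREE = "rat_free"
    RAT_INFESTED = "rat_infested"


class Stage(str, enum.Enum):
    """Macroscopic/histological reproductive stage of a collected fish."""

    SPAWNING_CAPABLE_FEMALE = "spawning_capable_female"
    REGENERATING_FEMALE = "regenerating_female"
    IMMATURE = "immature"
    TRANSITIONAL = "transitional"
    IP_MALE = "ip_male"


# plausibility window for total length (cm); overridable in the readers
DEFAULT_LENGTH_WINDOW = (5.0, 60.0)

# belt transect: 30 m x 5 m
DEFAULT_TRANSECT_AREA_M2 = 150.0

# underwater visual census records fish > 8 cm TL
SURVEY_MIN_LENGTH_CM = 8.0


@dataclass(frozen=True)
class FishRecord:
    """One collected fish.

    Lengths are total length in cm, wet weight in kg (as weighed in the
    field), otolith age in whole years (>= 1: young-of-year are never
    caught by this gear), gonad weight in g (formalin-fixed), %N by mass
    and d15N in permil from dorsal muscle.
    """

    fish_id: str
    island_id: str
    atoll_id: str
    treatment: Treatment
    total_length: float
    wet_weight: float
    age: int
    stage: Stage
    gonad_weight: float | None = None
    percent_N: float | None = None
    d15N: float | None = None
    collection_day: int | None = None

    def validate(self, length_window: tuple[float, float] = DEFAULT_LENGTH_WINDOW) -> None:
        lo, hi = length_window
        if not (self.total_length > 0 and lo <= self.total_length <= hi):
            raise RowValidationError(
                f"fish {self.fish_id}: total_length {self.total_length} cm outside "
                f"plausibility window [{lo}, {hi}]"
            )
        if not self.wet_weight > 0:
            raise RowValidationError(f"fish {self.fish_id}: wet_weight must be > 0 kg")
        if int(self.age) != self.age or self.age < 1:
            raise RowValidationError(
                f"fish {self.fish_id}: age must be a whole number of years >= 1, got {self.age}"
            )
        if self.gonad_weight is not None and self.gonad_weight < 0:
            raise RowValidationError(f"fish {self.fish_id}: gonad_weight must be >= 0 g")
        if self.percent_N is not None and not (0.0 <= self.percent_N <= 100.0):
            raise RowValidationError(f"fish {self.fish_id}: percent_N must lie in [0, 100]")
        for name in ("total_length", "wet_weight"):
            if not math.isfinite(getattr(self, name)):
                raise RowValidationError(f"fish {self.fish_id}: {name} is not finite")

    @property
    def gsi(self) -> float | None:
        """Gonadosomatic index (%), or None when gonad weight was not recorded."""
        if self.gonad_weight is None:
            return None
        return compute_gsi(self.gonad_weight, self.wet_weight)


@dataclass(frozen=True)
class TransectRecord:
    """One belt-transect survey: fixed area, zero or more (species, length) sightings."""

    island_id: str
    atoll_id: str
    treatment: Treatment
    transect_id: str
    area: float = DEFAULT_TRANSECT_AREA_M2
    observations: tuple[tuple[str, float], ...] = ()

    def validate(self, min_length: float = SURVEY_MIN_LENGTH_CM) -> None:
        if not self.area > 0:
            raise RowValidationError(f"transect {self.transect_id}: area must be > 0 m^2")
        for species, length in self.observations:
            if length < min_length:
                raise RowValidationError(
                    f"transect {self.transect_id}: observed {species} at {length} cm, "
                    f"below the {min_length} cm survey cutoff"
                )


@dataclass(frozen=True)
class IslandCovariates:
    """Per-island environmental covariates (seabird density, SST, wave exposure, NPP, area)."""

    island_id: str
    atoll_id: str
    treatment: Treatment
    covariates: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name, value in self.covariates.items():
            if not math.isfinite(value):
                raise RowValidationError(f"island {self.island_id}: covariate {name} not finite")
        sb = self.covariates.get("seabird_density")
        if sb is not None and sb < 0:
            raise RowValidationError(f"island {self.island_id}: seabird_density must be >= 0")


@dataclass(frozen=True)
class LengthWeightCoefficients:
    """Allometric length-weight coefficients W(g) = a * L(cm)^b for one species."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("length-weight coefficients a and b must both be > 0")


def compute_gsi(gonad_weight: float, wet_weight: float) -> float:
    """Gonadosomatic index: gonad mass as a percentage of body mass.

    Parameters
    ----------
    gonad_weight : float
        Gonad mass in g (>= 0).
    wet_weight : float
        Whole-body wet weight in kg (> 0); converted to g internally so the
        ratio is dimensionless.

    Returns
    -------
    float
        100 * gonad_weight / (wet_weight in g).
    """
    if wet_weight <= 0:
        raise ValueError(f"wet_weight must be > 0 kg, got {wet_weight}")
    if gonad_weight < 0:
        raise ValueError(f"gonad_weight must be >= 0 g, got {gonad_weight}")
    return 100.0 * gonad_weight / (wet_weight * 1000.0)


def length_to_weight(length: float, coeffs: LengthWeightCoefficients) -> float:
    """Power-law length-to-mass conversion, W(g) = a * L^b with L in cm."""
    if length < 0:
        raise ValueError(f"length must be >= 0 cm, got {length}")
    return coeffs.a * length ** coeffs.b


def transect_summaries(
    transects: Sequence[TransectRecord],
    coeffs: Mapping[str, LengthWeightCoefficients],
    species_filter: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-transect count, density and biomass.

    Zero transects are retained with (0, 0, 0) rows; the hurdle models need
    them. Density is reported per m^2 with the raw per-transect count kept
    alongside (the transect area, 150 m^2 by default, travels with the row).

    Raises
    ------
    ConfigurationError
        if a retained species has no length-weight coefficients.
    """
    keep = set(species_filter) if species_filter is not None else None
    rows = []
    for t in transects:
        obs = [o for o in t.observations if keep is None or o[0] in keep]
        missing = sorted({sp for sp, _ in obs} - set(coeffs))
        if missing:
            raise ConfigurationError(
                "no length-weight coefficients for species: " + ", ".join(missing)
            )
        biomass = sum(length_to_weight(L, coeffs[sp]) for sp, L in obs)
        rows.append(
            {
                "island_id": t.island_id,
                "atoll_id": t.atoll_id,
                "treatment": t.treatment.value,
                "transect_id": t.transect_id,
                "area_m2": t.area,
                "count": len(obs),
                "density_per_m2": len(obs) / t.area,
                "biomass_g": biomass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "island_id",
            "atoll_id",
            "treatment",
            "transect_id",
            "area_m2",
            "count",
            "density_per_m2",
            "biomass_g",
        ],
    )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

FISH_COLUMNS = {
    "fish_id": "fish_id",
    "island_id": "island_id",
    "atoll_id": "atoll_id",
    "treatment": "treatment",
    "total_length": "total_length_cm",
    "wet_weight": "wet_weight_kg",
    "age": "age_yr",
    "stage": "stage",
    "gonad_weight": "gonad_weight_g",
    "percent_N": "percent_N",
    "d15N": "d15N",
    "collection_day": "collection_day",
}

_FISH_REQUIRED = (
    "fish_id",
    "island_id",
    "atoll_id",
    "treatment",
    "total_length",
    "wet_weight",
    "age",
    "stage",
)

TRANSECT_COLUMNS = {
    "island_id": "island_id",
    "atoll_id": "atoll_id",
    "treatment": "treatment",
    "transect_id": "transect_id",
    "area": "area_m2",
    "species": "species",
    "length": "length_cm",
}

ISLAND_COLUMNS = {
    "island_id": "island_id",
    "atoll_id": "atoll_id",
    "treatment": "treatment",
}


def _resolve_columns(
    df: pd.DataFrame, defaults: Mapping[str, str], mapping: Mapping[str, str] | None,
    required: Iterable[str],
) -> dict[str, str]:
    cols = dict(defaults)
    if mapping:
        cols.update(mapping)
    for key in required:
        if cols[key] not in df.columns:
            raise SchemaError(f"required column '{cols[key]}' (field '{key}') is missing")
    return cols


def _parse_treatment(raw: str, row: int) -> Treatment:
    try:
        return Treatment(str(raw).strip().lower())
    except ValueError:
        raise RowValidationError(
            f"row {row}: unknown treatment '{raw}' (expected rat_free or rat_infested)"
        ) from None


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_fish_table(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    length_window: tuple[float, float] = DEFAULT_LENGTH_WINDOW,
) -> list[FishRecord]:
    """Read and validate a fish collection table.

    Rows violating invariants are reported together with their (1-based,
    header-exclusive) row numbers. Reproductive stage parses
    case-insensitively. Empty cells in optional columns yield absent fields.
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(df, FISH_COLUMNS, column_mapping, _FISH_REQUIRED)
    records: list[FishRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            try:
                length = float(row[cols["total_length"]])
                weight = float(row[cols["wet_weight"]])
                age_raw = float(row[cols["age"]])
            except (TypeError, ValueError) as exc:
                raise RowValidationError(f"non-numeric length/weight/age: {exc}") from None
            if not float(age_raw).is_integer():
                raise RowValidationError(f"age must be a whole number of years, got {age_raw}")
            stage_raw = str(row[cols["stage"]]).strip().lower()
            try:
                stage = Stage(stage_raw)
            except ValueError:
                raise RowValidationError(f"unknown stage '{row[cols['stage']]}'") from None
            rec = FishRecord(
                fish_id=str(row[cols["fish_id"]]),
                island_id=str(row[cols["island_id"]]),
                atoll_id=str(row[cols["atoll_id"]]),
                treatment=_parse_treatment(row[cols["treatment"]], i),
                total_length=length,
                wet_weight=weight,
                age=int(age_raw),
                stage=stage,
                gonad_weight=_optional_float(row.get(cols["gonad_weight"])),
                percent_N=_optional_float(row.get(cols["percent_N"])),
                d15N=_optional_float(row.get(cols["d15N"])),
                collection_day=(
                    None
                    if _optional_float(row.get(cols["collection_day"])) is None
                    else int(float(row[cols["collection_day"]]))
                ),
            )
            rec.validate(length_window)
            records.append(rec)
        except RowValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise RowValidationError("; ".join(errors))
    _check_treatment_constant(records)
    return records


def _check_treatment_constant(records: Sequence[FishRecord]) -> None:
    seen: dict[str, Treatment] = {}
    for r in records:
        prev = seen.setdefault(r.island_id, r.treatment)
        if prev is not r.treatment:
            raise RowValidationError(
                f"island {r.island_id} carries both treatments; treatment must be "
                "constant within an island"
            )


def write_fish_table(records: Sequence[FishRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                FISH_COLUMNS["fish_id"]: r.fish_id,
                FISH_COLUMNS["island_id"]: r.island_id,
                FISH_COLUMNS["atoll_id"]: r.atoll_id,
                FISH_COLUMNS["treatment"]: r.treatment.value,
                FISH_COLUMNS["total_length"]: r.total_length,
                FISH_COLUMNS["wet_weight"]: r.wet_weight,
                FISH_COLUMNS["age"]: r.age,
                FISH_COLUMNS["stage"]: r.stage.value,
                FISH_COLUMNS["gonad_weight"]: r.gonad_weight,
                FISH_COLUMNS["percent_N"]: r.percent_N,
                FISH_COLUMNS["d15N"]: r.d15N,
                FISH_COLUMNS["collection_day"]: r.collection_day,
            }
        )
    pd.DataFrame(rows, columns=list(FISH_COLUMNS.values())).to_csv(path, index=False)


def read_transect_table(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    min_length: float = SURVEY_MIN_LENGTH_CM,
) -> list[TransectRecord]:
    """Read a long-format survey table (one observed fish per row).

    A row with an empty species cell declares an empty transect: the
    transect is retained with no observations (a structural zero for the
    hurdle models).
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(
        df, TRANSECT_COLUMNS, column_mapping,
        ("island_id", "atoll_id", "treatment", "transect_id"),
    )
    grouped: dict[str, dict] = {}
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = raw._asdict()
        tid = str(row[cols["transect_id"]])
        area = _optional_float(row.get(cols["area"]))
        meta = grouped.setdefault(
            tid,
            {
                "island_id": str(row[cols["island_id"]]),
                "atoll_id": str(row[cols["atoll_id"]]),
                "treatment": _parse_treatment(row[cols["treatment"]], i),
                "area": area if area is not None else DEFAULT_TRANSECT_AREA_M2,
                "obs": [],
            },
        )
        species = row.get(cols["species"])
        length = _optional_float(row.get(cols["length"]))
        if species is not None and not (isinstance(species, float) and math.isnan(species)) and str(species) != "":
            if length is None:
                raise RowValidationError(f"row {i}: species given without a length")
            meta["obs"].append((str(species), length))
    records = [
        TransectRecord(
            island_id=m["island_id"],
            atoll_id=m["atoll_id"],
            treatment=m["treatment"],
            transect_id=tid,
            area=m["area"],
            observations=tuple(m["obs"]),
        )
        for tid, m in grouped.items()
    ]
    for rec in records:
        rec.validate(min_length)
    return records


def write_transect_table(records: Sequence[TransectRecord], path: str | Path) -> None:
    rows = []
    for t in records:
        base = {
            TRANSECT_COLUMNS["island_id"]: t.island_id,
            TRANSECT_COLUMNS["atoll_id"]: t.atoll_id,
            TRANSECT_COLUMNS["treatment"]: t.treatment.value,
            TRANSECT_COLUMNS["transect_id"]: t.transect_id,
            TRANSECT_COLUMNS["area"]: t.area,
        }
        if not t.observations:
            rows.append({**base, TRANSECT_COLUMNS["species"]: None, TRANSECT_COLUMNS["length"]: None})
        for species, length in t.observations:
            rows.append({**base, TRANSECT_COLUMNS["species"]: species, TRANSECT_COLUMNS["length"]: length})
    pd.DataFrame(rows, columns=list(TRANSECT_COLUMNS.values())).to_csv(path, index=False)


def read_island_table(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> list[IslandCovariates]:
    df = pd.read_csv(path)
    cols = _resolve_columns(df, ISLAND_COLUMNS, column_mapping, ISLAND_COLUMNS)
    id_cols = set(cols.values())
    records = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = raw._asdict()
        covs = {
            c: float(v)
            for c, v in row.items()
            if c not in id_cols and _optional_float(v) is not None
        }
        rec = IslandCovariates(
            island_id=str(row[cols["island_id"]]),
            atoll_id=str(row[cols["atoll_id"]]),
            treatment=_parse_treatment(row[cols["treatment"]], i),
            covariates=covs,
        )
        rec.validate()
        records.append(rec)
    return records


def write_island_table(records: Sequence[IslandCovariates], path: str | Path) -> None:
    cov_names: list[str] = []
    for r in records:
        for c in r.covariates:
            if c not in cov_names:
                cov_names.append(c)
    rows = [
        {
            "island_id": r.island_id,
            "atoll_id": r.atoll_id,
            "treatment": r.treatment.value,
            **{c: r.covariates.get(c) for c in cov_names},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["island_id", "atoll_id", "treatment", *cov_names]).to_csv(
        path, index=False
    )


def read_length_weight_table(path: str | Path) -> dict[str, LengthWeightCoefficients]:
    df = pd.read_csv(path)
    for col in ("species", "a", "b"):
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' is missing")
    return {
        str(row.species): LengthWeightCoefficients(a=float(row.a), b=float(row.b))
        for row in df.itertuples(index=False)
    }


def write_length_weight_table(
    coeffs: Mapping[str, LengthWeightCoefficients], path: str | Path
) -> None:
    pd.DataFrame(
        [{"species": sp, "a": c.a, "b": c.b} for sp, c in coeffs.items()],
        columns=["species", "a", "b"],
    ).to_csv(path, index=False)


def fish_to_frame(records: Sequence[FishRecord]) -> pd.DataFrame:
    """Convenience: fish records as a DataFrame with a derived ``gsi`` column."""
    return pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in records],
            "island_id": [r.island_id for r in records],
            "atoll_id": [r.atoll_id for r in records],
            "treatment": [r.treatment.value for r in records],
            "total_length": [r.total_length for r in records],
            "wet_weight": [r.wet_weight for r in records],
            "age": [r.age for r in records],
            "stage": [r.stage.value for r in records],
            "gonad_weight": [r.gonad_weight for r in records],
            "percent_N": [r.percent_N for r in records],
            "d15N": [r.d15N for r in records],
            "collection_day": [r.collection_day for r in records],
            "gsi": [r.gsi for r in records],
        }
    )
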