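"""Domain tables, CSV I/O and validation for the invasion/functional-diversity pipeline.

Four tables describe a study: a species table (origin status and body-mass
class), a species x function guild table, a site x species abundance matrix in
Moyle classes, and a site environmental table. All tables are pandas-backed;
CSV is the on-disk format (UTF-8, header row, "." decimal separator).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ECOLOGICAL_FUNCTIONS",
    "DEFAULT_GUILD_VOCABULARIES",
    "SpeciesTable",
    "TraitTable",
    "AbundanceMatrix",
    "EnvTable",
    "ValidationIssue",
    "ValidationReport",
    "DataError",
    "read_dataset",
    "validate_dataset",
]

#: The five ecological functions over which each species carries one guild label.
ECOLOGICAL_FUNCTIONS = ("feeding", "reproduction", "migration", "tolerance", "habitat_use")

#: Default guild vocabularies per ecological function. These are configurable
#: data, not a fixed taxonomy: studies declare their own vocabularies.
DEFAULT_GUILD_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "feeding": (
        "omnivorous",
        "invertivorous",
        "piscivorous",
        "herbivorous",
        "planktivorous",
        "detritivorous",
    ),
    "reproduction": (
        "phytophilic",
        "lithophilic",
        "psammophilic",
        "phytolithophilic",
        "ostracophilic",
        "pelagophilic",
    ),
    "migration": ("resident", "potamodromous", "anadromous", "catadromous"),
    "tolerance": ("intolerant", "intermediate", "tolerant"),
    "habitat_use": ("benthic", "water_column", "eurytopic", "limnophilic", "rheophilic"),
}

ORIGIN_LEVELS = ("native", "exotic")
BODY_MASS_CLASSES = (1, 2, 3)
MOYLE_MIN, MOYLE_MAX = 0, 5  # 0 encodes absence; field classes run 1..5

ENV_COORD_COLUMNS = ("longitude", "latitude")
ENV_PHYSCHEM_COLUMNS = (
    "water_temperature",
    "electrical_conductivity",
    "cod",
    "bod",
    "tss",
    "total_phosphorus",
    "ammonia",
    "nitrate",
)
ENV_LANDCOVER_COLUMNS = (
    "urban",
    "agricultural",
    "forest",
    "other_natural",
    "freshwater",
    "brackish_water",
)
ENV_REQUIRED_COLUMNS = (
    ENV_COORD_COLUMNS + ("altitude",) + ENV_PHYSCHEM_COLUMNS + ENV_LANDCOVER_COLUMNS
    + ("stream_order", "is_canal")
)


class DataError(ValueError):
    """Raised for structurally invalid input tables."""


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    subject: str  # site or species id ("" when global)
    message: str


@dataclasses.dataclass
class ValidationReport:
    issues: list[ValidationIssue] = dataclasses.field(default_factory=list)

    def add(self, severity: str, subject: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, subject, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __iter__(self):
        return iter(self.issues)

    def __len__(self) -> int:
        return len(self.issues)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{what}: missing required column(s) {missing}")


class SpeciesTable:
    """Per-species identity: origin (native/exotic) and adult body-mass class.

    Body-mass classes proxy average adult size: 1 (small, up to ~150 g),
    2 (medium, ~150-400 g), 3 (large, over ~400 g).
    """

    required_columns = ("species_id", "origin", "body_mass_class")

    def __init__(self, data: pd.DataFrame):
        _require_columns(data, self.required_columns, "species table")
        df = data.copy()
        df["species_id"] = df["species_id"].astype(str)
        if df["species_id"].duplicated().any():
            dups = sorted(df.loc[df["species_id"].duplicated(), "species_id"])
            raise DataError(f"species table: duplicated species_id {dups}")
        bad = ~df["origin"].isin(ORIGIN_LEVELS)
        if bad.any():
            raise DataError(
                f"species table: origin must be one of {ORIGIN_LEVELS}; "
                f"offending species {sorted(df.loc[bad, 'species_id'])}"
            )
        df["body_mass_class"] = df["body_mass_class"].astype(int)
        bad = ~df["body_mass_class"].isin(BODY_MASS_CLASSES)
        if bad.any():
            raise DataError(
                f"species table: body_mass_class must be in {BODY_MASS_CLASSES}; "
                f"offending species {sorted(df.loc[bad, 'species_id'])}"
            )
        self.data = df.set_index("species_id", drop=False)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_ids(self, subset: str) -> list[str]:
        """Species ids for a subset label in {'all', 'native', 'exotic'}."""
        if subset == "all":
            return self.species_ids
        if subset not in ORIGIN_LEVELS:
            raise ValueError(f"unknown subset {subset!r}; expected all/native/exotic")
        return list(self.data.index[self.data["origin"] == subset])

    @property
    def origin(self) -> pd.Series:
        return self.data["origin"]

    @property
    def body_mass_class(self) -> pd.Series:
        return self.data["body_mass_class"]

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpeciesTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesTable) and self.data.equals(other.data)


class TraitTable:
    """Species x ecological-function guild assignments (one label per function)."""

    def __init__(
        self,
        data: pd.DataFrame,
        vocabularies: Mapping[str, Sequence[str]] | None = None,
    ):
        self.vocabularies = {
            fn: tuple(v) for fn, v in (vocabularies or DEFAULT_GUILD_VOCABULARIES).items()
        }
        _require_columns(data, ("species_id",) + ECOLOGICAL_FUNCTIONS, "trait table")
        df = data.copy()
        df["species_id"] = df["species_id"].astype(str)
        if df["species_id"].duplicated().any():
            dups = sorted(df.loc[df["species_id"].duplicated(), "species_id"])
            raise DataError(f"trait table: duplicated species_id {dups}")
        for fn in ECOLOGICAL_FUNCTIONS:
            vocab = self.vocabularies[fn]
            bad = ~df[fn].isin(vocab)
            if bad.any():
                labels = sorted(set(df.loc[bad, fn].astype(str)))
                raise DataError(
                    f"trait table: function {fn!r} has label(s) {labels} outside "
                    f"declared vocabulary {list(vocab)}"
                )
        self.data = df.set_index("species_id", drop=False)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def guilds(self, species: Sequence[str] | None = None) -> pd.DataFrame:
        """Guild labels (species x 5 functions), optionally for a species subset."""
        df = self.data[list(ECOLOGICAL_FUNCTIONS)]
        if species is None:
            return df
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise DataError(f"trait table: unknown species {missing}")
        return df.loc[list(species)]

    @classmethod
    def read_csv(cls, path: str | Path, vocabularies=None) -> "TraitTable":
        return cls(pd.read_csv(path), vocabularies=vocabularies)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, TraitTable) and self.data.equals(other.data)


class AbundanceMatrix:
    """Site x species grid of Moyle abundance classes (0 = absent, 1..5 observed).

    Stored wide: one row per site, one integer column per species.
    """

    def __init__(self, data: pd.DataFrame):
        if "site_id" in data.columns:
            data = data.set_index(data["site_id"].astype(str)).drop(columns="site_id")
        df = data.copy()
        df.index = df.index.astype(str)
        df.index.name = "site_id"
        if df.index.duplicated().any():
            raise DataError(
                f"abundance matrix: duplicated site_id {sorted(df.index[df.index.duplicated()])}"
            )
        try:
            df = df.astype(int)
        except (TypeError, ValueError) as exc:
            raise DataError(f"abundance matrix: non-integer entries ({exc})") from exc
        bad = (df.values < MOYLE_MIN) | (df.values > MOYLE_MAX)
        if bad.any():
            r, c = map(int, next(zip(*bad.nonzero())))
            raise DataError(
                f"abundance matrix: value {df.iat[r, c]} out of Moyle range "
                f"[{MOYLE_MIN}, {MOYLE_MAX}] at site {df.index[r]!r}, "
                f"species {df.columns[c]!r}"
            )
        self.data = df

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_csv(cls, path: str | Path) -> "AbundanceMatrix":
        return cls(pd.read_csv(path))

    @classmethod
    def read_long_csv(cls, path: str | Path) -> "AbundanceMatrix":
        """Read a long-format table with columns site_id, species_id, moyle_class."""
        long = pd.read_csv(path)
        _require_columns(long, ("site_id", "species_id", "moyle_class"), "long abundance table")
        wide = (
            long.pivot_table(
                index="site_id", columns="species_id", values="moyle_class", fill_value=0
            )
            .astype(int)
        )
        wide.columns.name = None
        return cls(wide)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=True)

    def __eq__(self, other) -> bool:
        return isinstance(other, AbundanceMatrix) and self.data.equals(other.data)


class EnvTable:
    """Per-site environment: coordinates, altitude, physicochemistry, land cover,
    stream order and canal flag. Unknown extra columns are preserved untouched."""

    def __init__(self, data: pd.DataFrame):
        _require_columns(data, ("site_id",) + ENV_REQUIRED_COLUMNS, "environmental table")
        df = data.copy()
        df["site_id"] = df["site_id"].astype(str)
        if df["site_id"].duplicated().any():
            dups = sorted(df.loc[df["site_id"].duplicated(), "site_id"])
            raise DataError(f"environmental table: duplicated site_id {dups}")
        df["is_canal"] = df["is_canal"].astype(bool)
        df["stream_order"] = df["stream_order"].astype(int)
        for col in ENV_LANDCOVER_COLUMNS:
            vals = df[col].astype(float)
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                raise DataError(
                    f"environmental table: land-cover share {col!r} outside [0, 1] "
                    f"at site(s) {sorted(df.loc[bad, 'site_id'])}"
                )
        self.data = df.set_index("site_id", drop=False)

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def altitude(self) -> pd.Series:
        return self.data["altitude"]

    @classmethod
    def read_csv(cls, path: str | Path) -> "EnvTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, EnvTable) and self.data.equals(other.data)


def read_dataset(
    species_path: str | Path,
    traits_path: str | Path,
    abundance_path: str | Path,
    env_path: str | Path,
    vocabularies: Mapping[str, Sequence[str]] | None = None,
) -> tuple[SpeciesTable, TraitTable, AbundanceMatrix, EnvTable]:
    """Read and cross-reference the four dataset tables from CSV files.

    Raises :class:`DataError` when a species in the abundance matrix is absent
    from the species table, or any table violates its declared schema.
    """
    species = SpeciesTable.read_csv(species_path)
    traits = TraitTable.read_csv(traits_path, vocabularies=vocabularies)
    abundance = AbundanceMatrix.read_csv(abundance_path)
    env = EnvTable.read_csv(env_path)

    unknown = [s for s in abundance.species_ids if s not in species.data.index]
    if unknown:
        raise DataError(f"abundance matrix references species not in species table: {unknown}")
    return species, traits, abundance, env


def validate_dataset(
    species: SpeciesTable,
    traits: TraitTable,
    abundance: AbundanceMatrix,
    env: EnvTable,
) -> ValidationReport:
    """Cross-reference and range-check the four tables without mutating them.

    The report is empty exactly when the dataset is internally consistent:
    every abundance/trait species exists in the species table and vice versa,
    abundance sites match environmental sites, no site is empty, and numeric
    ranges hold. Idempotent and side-effect free.
    """
    report = ValidationReport()

    sp_ids = set(species.species_ids)
    for sid in abundance.species_ids:
        if sid not in sp_ids:
            report.add("error", sid, "species in abundance matrix missing from species table")
    for sid in traits.species_ids:
        if sid not in sp_ids:
            report.add("error", sid, "species in trait table missing from species table")
    trait_ids = set(traits.species_ids)
    for sid in species.species_ids:
        if sid not in trait_ids:
            report.add("error", sid, "species has no trait (guild) record")
        if sid not in abundance.species_ids:
            report.add("warning", sid, "species never observed in abundance matrix")

    env_ids = set(env.site_ids)
    for site in abundance.site_ids:
        if site not in env_ids:
            report.add("error", site, "site in abundance matrix missing from environmental table")
    ab_ids = set(abundance.site_ids)
    for site in env.site_ids:
        if site not in ab_ids:
            report.add("warning", site, "site in environmental table has no abundance row")

    row_sums = abundance.data.sum(axis=1)
    for site in abundance.data.index[row_sums == 0]:
        report.add("warning", site, "site has all-zero abundances (empty community)")

    if not env.data["altitude"].map(pd.notna).all():
        for site in env.data.index[env.data["altitude"].isna()]:
            report.add("error", site, "altitude missing")
    return report


def drop_empty_sites(abundance: AbundanceMatrix) -> AbundanceMatrix:
    """Return a copy with all-zero sites removed, warning for each."""
    row_sums = abundance.data.sum(axis=1)
    empty = list(abundance.data.index[row_sums == 0])
    if empty:
        warnings.warn(f"dropping {len(empty)} empty site(s): {empty}", stacklevel=2)
        return AbundanceMatrix(abundance.data.loc[row_sums > 0])
    return abundance
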