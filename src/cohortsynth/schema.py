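"""Cohort schema: the data dictionary driving estimation and simulation.

A :class:`CohortSchema` declares, for a longitudinal study with repeated
clinic visits ("waves"), which measurement is recorded in which column and
how each column is synthesised:

* ``mvn`` -- continuous measurements drawn jointly from a multivariate
  normal whose correlation structure is estimated from the source data;
* ``binary`` -- the sex indicator (coded 1 = male, 2 = female), simulated
  from a logistic model fitted on the continuous columns;
* ``derived_bmi`` -- body-mass index, computed from the simulated weight
  and height of the same wave, never drawn independently;
* ``independent_age`` -- exact age at clinic attendance, drawn from an
  independent normal per wave.

The bundled default schema describes the eleven cardiac and anthropometric
variables measured across nine ALSPAC childhood clinics (71 columns).
Schemas are plain YAML so the pipeline can be re-targeted to another cohort
without code changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import yaml

__all__ = [
    "VARIABLE_KINDS",
    "KIND_UNITS",
    "ClinicWave",
    "ColumnSpec",
    "CohortSchema",
    "SchemaError",
    "load_schema",
    "coverage_matrix",
]

#: the eleven variable kinds, in data-dictionary order
VARIABLE_KINDS = (
    "sex",
    "age",
    "height",
    "sitting_height",
    "waist",
    "hip",
    "weight",
    "sbp",
    "dbp",
    "pulse",
    "bmi",
)

KIND_UNITS = {
    "sex": "code",
    "age": "years",
    "height": "cm",
    "sitting_height": "cm",
    "waist": "cm",
    "hip": "cm",
    "weight": "kg",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "pulse": "beats/min",
    "bmi": "kg/m²",
}

#: generation role implied by each variable kind
_KIND_ROLE = {
    "sex": "binary",
    "age": "independent_age",
    "bmi": "derived_bmi",
}


class SchemaError(ValueError):
    """Raised when a schema config is malformed or violates an invariant."""


@dataclass(frozen=True)
class ClinicWave:
    """A scheduled assessment visit, e.g. the "Focus @ 7" clinic."""

    id: str
    nominal_age_years: int


@dataclass(frozen=True)
class ColumnSpec:
    """One column of the cohort table and how it is generated."""

    column_name: str
    source_name: str
    kind: str
    wave: str | None  # wave id; None only for the wave-less sex column
    role: str = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise SchemaError(
                f"column {self.column_name!r}: unknown kind {self.kind!r}"
            )
        object.__setattr__(self, "role", _KIND_ROLE.get(self.kind, "mvn"))


@dataclass
class CohortSchema:
    """Ordered collection of column specs plus the clinic-wave calendar."""

    name: str
    waves: list[ClinicWave]
    columns: list[ColumnSpec]

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    @property
    def column_names(self) -> list[str]:
        return [c.column_name for c in self.columns]

    @property
    def wave_ids(self) -> list[str]:
        return [w.id for w in self.waves]

    def wave(self, wave_id: str) -> ClinicWave:
        for w in self.waves:
            if w.id == wave_id:
                return w
        raise KeyError(wave_id)

    def columns_of_role(self, role: str) -> list[ColumnSpec]:
        return [c for c in self.columns if c.role == role]

    @property
    def mvn_columns(self) -> list[str]:
        return [c.column_name for c in self.columns if c.role == "mvn"]

    @property
    def age_columns(self) -> list[str]:
        return [c.column_name for c in self.columns if c.role == "independent_age"]

    @property
    def bmi_columns(self) -> list[str]:
        return [c.column_name for c in self.columns if c.role == "derived_bmi"]

    @property
    def sex_column(self) -> str:
        (col,) = [c.column_name for c in self.columns if c.role == "binary"]
        return col

    @property
    def continuous_columns(self) -> list[str]:
        """Every non-sex column, in schema order (mvn + bmi + age)."""
        return [c.column_name for c in self.columns if c.role != "binary"]

    def find(self, column_name: str) -> ColumnSpec:
        for c in self.columns:
            if c.column_name == column_name:
                return c
        raise KeyError(column_name)

    def same_wave_column(self, wave_id: str, kind: str) -> str:
        """Name of the column of ``kind`` at ``wave_id`` (KeyError if absent)."""
        for c in self.columns:
            if c.wave == wave_id and c.kind == kind:
                return c.column_name
        raise KeyError((wave_id, kind))

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        names = self.column_names
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate column names: {sorted(dupes)}")

        wave_ids = self.wave_ids
        if len(set(wave_ids)) != len(wave_ids):
            raise SchemaError("duplicate wave ids")
        ages = [w.nominal_age_years for w in self.waves]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise SchemaError("wave nominal ages must strictly increase")

        for c in self.columns:
            if c.kind == "sex":
                if c.wave is not None:
                    raise SchemaError("sex column must be wave-less")
            else:
                if c.wave is None:
                    raise SchemaError(
                        f"column {c.column_name!r} must declare a wave"
                    )
                if c.wave not in wave_ids:
                    raise SchemaError(
                        f"column {c.column_name!r}: unknown wave {c.wave!r}"
                    )

        n_sex = len(self.columns_of_role("binary"))
        if n_sex != 1:
            raise SchemaError(f"expected exactly one sex column, found {n_sex}")

        # BMI is derived from same-wave height and weight, which must exist
        for c in self.columns_of_role("derived_bmi"):
            for needed in ("height", "weight"):
                try:
                    self.same_wave_column(c.wave, needed)
                except KeyError:
                    raise SchemaError(
                        f"BMI column {c.column_name!r} at wave {c.wave} "
                        f"has no same-wave {needed} column"
                    ) from None

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "waves": [
                {"id": w.id, "nominal_age_years": w.nominal_age_years}
                for w in self.waves
            ],
            "columns": [
                {
                    "name": c.column_name,
                    "source": c.source_name,
                    "kind": c.kind,
                    **({"wave": c.wave} if c.wave is not None else {}),
                }
                for c in self.columns
            ],
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSchema":
        try:
            waves = [
                ClinicWave(id=str(w["id"]), nominal_age_years=int(w["nominal_age_years"]))
                for w in raw["waves"]
            ]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed wave entry: {exc}") from exc
        columns = []
        for entry in raw.get("columns", []):
            try:
                columns.append(
                    ColumnSpec(
                        column_name=str(entry["name"]),
                        source_name=str(entry.get("source", entry["name"])),
                        kind=str(entry["kind"]),
                        wave=(str(entry["wave"]) if "wave" in entry and entry["wave"] is not None else None),
                    )
                )
            except KeyError as exc:
                raise SchemaError(
                    f"malformed column entry {entry!r}: missing {exc}"
                ) from exc
        return cls(name=str(raw.get("name", "unnamed")), waves=waves, columns=columns)


def load_schema(config_path: Union[str, Path] = "bundled") -> CohortSchema:
    """Load a cohort schema from a YAML config, or the packaged default.

    ``load_schema("bundled")`` returns the ALSPAC childhood-clinic schema
    shipped with the package (71 columns, 9 waves, 11 variable kinds).
    """
    if config_path == "bundled":
        ref = importlib.resources.files("cohortsynth.data") / "alspac_schema.yaml"
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        path = Path(config_path)
        if not path.exists():
            raise SchemaError(f"schema config not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise SchemaError("schema config must be a mapping")
    return CohortSchema.from_dict(raw)


def coverage_matrix(schema: CohortSchema) -> pd.DataFrame:
    """Boolean kind × wave matrix: which measurement exists at which clinic.

    The sex row is all-true (sex is recorded once and applies to every
    wave); other cells are true iff the schema declares a column of that
    kind at that wave.
    """
    kinds = [k for k in VARIABLE_KINDS]
    mat = pd.DataFrame(False, index=kinds, columns=schema.wave_ids, dtype=bool)
    for c in schema.columns:
        if c.kind == "sex":
            mat.loc["sex", :] = True
        else:
            mat.loc[c.kind, c.wave] = True
    return mat
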