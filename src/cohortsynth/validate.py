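"""Moment-matching validation of a synthetic cohort against its source.

A synthetic table is considered faithful when the estimated means,
standard deviations, pairwise correlations of the measurement block, the
sex proportion and the BMI identity all agree with the (complete-case)
source within Monte-Carlo-derived tolerances. The default tolerances are
4-standard-error bounds at the two sample sizes, not study constants, and
every one is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd

from .preprocess import ages_months_to_years
from .schema import CohortSchema

__all__ = ["Tolerances", "ColumnComparison", "ValidationReport", "compare_moments"]


@dataclass(frozen=True)
class Tolerances:
    """Pass/fail thresholds for :func:`compare_moments`.

    All defaults are 4-standard-error Monte-Carlo bounds, not study
    constants. ``abs_std_diff`` (|Δmean|/σ_src) defaults to
    4/√n_syn + 4/√n_src, computed at comparison time when left ``None``.
    The SD, correlation and sex-proportion bounds are calibrated for
    synthetic samples of at least 100,000 rows; for smaller outputs they
    are widened by √(100000/n_syn) (sampling error scales as 1/√n), unless
    ``small_sample_scaling`` is disabled.
    """

    abs_std_diff: float | None = None
    rel_sd_diff: float = 0.02
    max_abs_corr_diff: float = 0.02
    sex_proportion_diff: float = 0.01
    bmi_identity_rel: float = 1e-9
    small_sample_scaling: bool = True
    calibration_n: int = 100_000

    def resolved_abs_std_diff(self, n_src: int, n_syn: int) -> float:
        if self.abs_std_diff is not None:
            return self.abs_std_diff
        return 4.0 / np.sqrt(n_syn) + 4.0 / np.sqrt(n_src)

    def scale_factor(self, n_syn: int) -> float:
        if not self.small_sample_scaling or n_syn >= self.calibration_n:
            return 1.0
        return float(np.sqrt(self.calibration_n / n_syn))


@dataclass
class ColumnComparison:
    mean_src: float
    mean_syn: float
    abs_std_diff: float  # |mean_syn - mean_src| / sd_src
    sd_src: float
    sd_syn: float
    rel_sd_diff: float  # |sd_syn - sd_src| / sd_src


@dataclass
class ValidationReport:
    per_column: dict[str, ColumnComparison]
    max_abs_corr_diff: float
    sex_prop_src: float
    sex_prop_syn: float
    bmi_identity_violations: int
    n_src: int
    n_syn: int
    abs_std_diff_tol: float
    rel_sd_diff_tol: float
    max_abs_corr_diff_tol: float
    sex_proportion_diff_tol: float
    overall_pass: bool = field(init=False)

    def __post_init__(self) -> None:
        self.overall_pass = (
            all(
                c.abs_std_diff <= self.abs_std_diff_tol
                and c.rel_sd_diff <= self.rel_sd_diff_tol
                for c in self.per_column.values()
            )
            and self.max_abs_corr_diff <= self.max_abs_corr_diff_tol
            and abs(self.sex_prop_syn - self.sex_prop_src) <= self.sex_proportion_diff_tol
            and self.bmi_identity_violations == 0
        )

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "ValidationReport":
        raw = dict(raw)
        raw.pop("overall_pass", None)
        raw["per_column"] = {
            k: ColumnComparison(**v) for k, v in raw["per_column"].items()
        }
        return cls(**raw)

    def save_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load_json(cls, path: Union[str, Path]) -> "ValidationReport":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_text(self) -> str:
        lines = [
            f"validation: source n={self.n_src}, synthetic n={self.n_syn}",
            f"  worst standardized mean diff : "
            f"{max(c.abs_std_diff for c in self.per_column.values()):.5f}"
            f"  (tol {self.abs_std_diff_tol:.5f})",
            f"  worst relative SD diff       : "
            f"{max(c.rel_sd_diff for c in self.per_column.values()):.5f}"
            f"  (tol {self.rel_sd_diff_tol:.5f})",
            f"  max |corr diff| (mvn block)  : {self.max_abs_corr_diff:.5f}"
            f"  (tol {self.max_abs_corr_diff_tol:.5f})",
            f"  sex proportion src/syn       : {self.sex_prop_src:.4f} / "
            f"{self.sex_prop_syn:.4f}  (tol {self.sex_proportion_diff_tol})",
            f"  BMI identity violations      : {self.bmi_identity_violations}",
            f"  overall: {'PASS' if self.overall_pass else 'FAIL'}",
        ]
        return "\n".join(lines)


def _corr(block: np.ndarray) -> np.ndarray:
    z = (block - block.mean(axis=0)) / block.std(axis=0, ddof=1)
    return (z.T @ z) / (len(block) - 1)


def compare_moments(
    source_clean: pd.DataFrame,
    synthetic: pd.DataFrame,
    schema: CohortSchema,
    tolerances: Tolerances | None = None,
    source_ages_in: Literal["months", "years"] = "months",
) -> ValidationReport:
    """Compare source and synthetic moments column by column.

    The source must be complete-case cleaned; its age columns are converted
    from months to years (the unit the synthetic table carries) unless
    ``source_ages_in="years"``. Mean and SD comparisons cover every
    continuous column (measurements, BMI and age); the correlation check
    covers the jointly-simulated measurement block only. The estimators
    match those used for parameter estimation (n-1 denominators).
    """
    tolerances = tolerances or Tolerances()
    for name, table in (("source", source_clean), ("synthetic", synthetic)):
        missing = [c for c in schema.column_names if c not in table.columns]
        if missing:
            raise ValueError(f"{name} table lacks schema columns: {missing}")
    if source_clean[schema.column_names].isna().any().any():
        raise ValueError("source table must be complete-case cleaned first")

    if source_ages_in == "months":
        source_clean = ages_months_to_years(source_clean, schema)

    n_src, n_syn = len(source_clean), len(synthetic)
    abs_tol = tolerances.resolved_abs_std_diff(n_src, n_syn)
    scale = tolerances.scale_factor(n_syn)

    per_column: dict[str, ColumnComparison] = {}
    for col in schema.continuous_columns:
        xs = source_clean[col].to_numpy(dtype=float)
        xt = synthetic[col].to_numpy(dtype=float)
        sd_src = float(np.std(xs, ddof=1))
        sd_syn = float(np.std(xt, ddof=1))
        mean_src = float(np.mean(xs))
        mean_syn = float(np.mean(xt))
        per_column[col] = ColumnComparison(
            mean_src=mean_src,
            mean_syn=mean_syn,
            abs_std_diff=abs(mean_syn - mean_src) / sd_src,
            sd_src=sd_src,
            sd_syn=sd_syn,
            rel_sd_diff=abs(sd_syn - sd_src) / sd_src,
        )

    mvn = schema.mvn_columns
    corr_src = _corr(source_clean[mvn].to_numpy(dtype=float))
    corr_syn = _corr(synthetic[mvn].to_numpy(dtype=float))
    max_corr_diff = float(np.max(np.abs(corr_src - corr_syn)))

    sex = schema.sex_column
    prop_src = float((source_clean[sex].to_numpy() == 2).mean())
    prop_syn = float((synthetic[sex].to_numpy() == 2).mean())

    violations = 0
    for col in schema.bmi_columns:
        spec = schema.find(col)
        w = synthetic[schema.same_wave_column(spec.wave, "weight")].to_numpy(dtype=float)
        h = synthetic[schema.same_wave_column(spec.wave, "height")].to_numpy(dtype=float)
        expected = w / (h / 100.0) ** 2
        actual = synthetic[col].to_numpy(dtype=float)
        rel = np.abs(actual - expected) / np.maximum(np.abs(expected), 1e-300)
        violations += int((rel > tolerances.bmi_identity_rel).sum())

    return ValidationReport(
        per_column=per_column,
        max_abs_corr_diff=max_corr_diff,
        sex_prop_src=prop_src,
        sex_prop_syn=prop_syn,
        bmi_identity_violations=violations,
        n_src=n_src,
        n_syn=n_syn,
        abs_std_diff_tol=abs_tol,
        rel_sd_diff_tol=tolerances.rel_sd_diff * scale,
        max_abs_corr_diff_tol=tolerances.max_abs_corr_diff * scale,
        sex_proportion_diff_tol=tolerances.sex_proportion_diff * scale,
    )
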