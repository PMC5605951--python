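"""Synthetic SOURCE cohort generator.

The real cohort extract behind the bundled schema is access-controlled, so
this module fabricates a stand-in with the same shape: 15,445 children, 71
columns, growth-curve means and SDs per clinic, AR(1)-style decay of
within-trait correlations across clinic ages, cross-trait correlations at
equal age, additive sex shifts, exact ages in months around each clinic's
nominal age, and a missingness plan under which complete-case filtering
leaves exactly 1,593 fully observed rows.

All trajectory numbers are invented fixture defaults with plausible
magnitudes for a UK childhood cohort (the governed source publishes no
moments); every one is overridable through :class:`FixtureConfig`. The
exact complete-case count is achieved with a deterministic completion mask
-- a fixed-size random subset of rows left fully observed -- rather than by
tuning attendance probabilities, which makes the count a testable target.

Correlation between column (kind k, clinic age a) and (kind l, clinic age
b) is modelled separably as ``C[k,l] * sqrt(rho_k * rho_l) ** |a - b|``,
where ``C`` is the equal-age cross-trait correlation matrix and ``rho_k``
the per-year within-trait decay. BMI columns are computed from the fixture
height and weight (as in real data), never drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import repair_correlation
from .schema import CohortSchema

__all__ = [
    "MissingnessPlan",
    "FixtureConfig",
    "implied_mvn_correlation",
    "generate_source_cohort",
    "apply_missingness",
    "default_source",
]

# per-clinic (mean, SD) of each measurement kind; keys are wave ids,
# restricted to the waves where the bundled schema records the kind
_TRAJECTORIES: dict[str, dict[str, tuple[float, float]]] = {
    "height": {
        "F7": (125.0, 5.5), "F8": (130.5, 5.7), "F9": (136.0, 6.0),
        "F10": (141.0, 6.3), "F11": (147.0, 6.8), "TF1": (153.0, 7.5),
        "TF2": (160.0, 8.0), "TF3": (168.0, 8.5), "TF4": (172.0, 8.5),
    },
    "sitting_height": {
        "F7": (68.0, 3.0), "F9": (72.0, 3.2), "F10": (74.0, 3.4),
        "F11": (77.0, 3.7), "TF1": (80.0, 4.0), "TF3": (88.0, 4.5),
    },
    "waist": {
        "F7": (55.0, 5.0), "F9": (58.0, 6.0), "F10": (60.0, 6.5),
        "F11": (63.0, 7.0), "TF1": (66.0, 7.5), "TF2": (68.0, 8.0),
        "TF3": (71.0, 8.5),
    },
    "hip": {"F7": (62.0, 5.0), "F9": (68.0, 6.0), "F11": (75.0, 7.0)},
    "weight": {
        "F7": (26.0, 4.5), "F8": (29.0, 5.2), "F9": (33.0, 6.2),
        "F10": (37.0, 7.2), "F11": (42.0, 8.5), "TF2": (51.0, 10.0),
        "TF3": (58.0, 11.0), "TF4": (64.0, 12.0),
    },
    "sbp": {
        "F7": (99.0, 9.0), "F9": (102.0, 9.0), "F10": (104.0, 10.0),
        "F11": (106.0, 10.0), "TF1": (108.0, 10.0), "TF2": (111.0, 11.0),
        "TF3": (115.0, 11.0), "TF4": (117.0, 11.0),
    },
    "dbp": {
        "F7": (57.0, 7.0), "F9": (58.0, 7.0), "F10": (59.0, 7.0),
        "F11": (60.0, 7.0), "TF1": (61.0, 7.0), "TF2": (62.0, 8.0),
        "TF3": (64.0, 8.0), "TF4": (65.0, 8.0),
    },
    "pulse": {
        "F7": (82.0, 10.0), "F9": (80.0, 10.0), "F11": (77.0, 10.0),
        "TF1": (75.0, 10.0), "TF2": (73.0, 10.0), "TF3": (70.0, 10.0),
        "TF4": (68.0, 10.0),
    },
}

#: per-year AR(1) decay of within-trait correlation across clinic ages
_WITHIN_TRAIT_RHO = {
    "height": 0.97, "sitting_height": 0.96, "waist": 0.90, "hip": 0.90,
    "weight": 0.95, "sbp": 0.80, "dbp": 0.78, "pulse": 0.75,
}

_MVN_KINDS = ("height", "sitting_height", "waist", "hip", "weight", "sbp", "dbp", "pulse")

#: equal-age cross-trait correlations (order = _MVN_KINDS)
_CROSS_TRAIT = np.array([
    [1.00, 0.85, 0.40, 0.55, 0.70, 0.20, 0.10, -0.05],
    [0.85, 1.00, 0.40, 0.55, 0.65, 0.20, 0.10, -0.05],
    [0.40, 0.40, 1.00, 0.75, 0.80, 0.25, 0.15, 0.05],
    [0.55, 0.55, 0.75, 1.00, 0.80, 0.20, 0.10, 0.00],
    [0.70, 0.65, 0.80, 0.80, 1.00, 0.30, 0.20, 0.05],
    [0.20, 0.20, 0.25, 0.20, 0.30, 1.00, 0.60, 0.15],
    [0.10, 0.10, 0.15, 0.10, 0.20, 0.60, 1.00, 0.20],
    [-0.05, -0.05, 0.05, 0.00, 0.05, 0.15, 0.20, 1.00],
])

# additive shift for females (code 2) relative to males; girls are slightly
# ahead through early puberty, boys overtake by 15-17
_SEX_EFFECTS: dict[str, dict[str, float]] = {
    "height": {"F7": 0.5, "F8": 0.5, "F9": 0.5, "F10": 0.5, "F11": 1.0,
               "TF1": 1.0, "TF2": -2.0, "TF3": -9.0, "TF4": -13.0},
    "sitting_height": {"F7": 0.3, "F9": 0.3, "F10": 0.3, "F11": 0.5,
                       "TF1": 0.5, "TF3": -4.5},
    "waist": {"F7": -1.0, "F9": -1.0, "F10": -1.0, "F11": -1.0, "TF1": -1.0,
              "TF2": -2.0, "TF3": -4.0},
    "hip": {"F7": 1.0, "F9": 1.5, "F11": 2.0},
    "weight": {"F7": 0.3, "F8": 0.3, "F9": 0.5, "F10": 0.5, "F11": 0.5,
               "TF2": -1.0, "TF3": -6.0, "TF4": -9.0},
    "sbp": {"TF2": -2.0, "TF3": -5.0, "TF4": -7.0},
    "dbp": {"TF3": -1.0, "TF4": -2.0},
    "pulse": {"TF3": 3.0, "TF4": 4.0},
}

#: per-wave clinic attendance probabilities (declining with age)
_ATTENDANCE = {
    "F7": 0.75, "F8": 0.70, "F9": 0.72, "F10": 0.68, "F11": 0.65,
    "TF1": 0.60, "TF2": 0.55, "TF3": 0.50, "TF4": 0.45,
}


@dataclass
class MissingnessPlan:
    """Per-wave attendance probabilities plus a deterministic completion
    mask size: exactly ``n_complete_target`` rows stay fully observed."""

    attendance: dict[str, float] = field(default_factory=lambda: dict(_ATTENDANCE))
    n_complete_target: int = 1593


@dataclass
class FixtureConfig:
    n: int = 15445
    seed: int = 2017
    trait_trajectories: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TRAJECTORIES.items()}
    )
    within_trait_corr: dict[str, float] = field(
        default_factory=lambda: dict(_WITHIN_TRAIT_RHO)
    )
    cross_trait_corr: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            _CROSS_TRAIT.copy(), index=list(_MVN_KINDS), columns=list(_MVN_KINDS)
        )
    )
    sex_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _SEX_EFFECTS.items()}
    )
    sex_proportion_female: float = 0.49
    age_attendance_lag_years: float = 0.4
    age_jitter_sd: float = 0.25  # years
    missingness_plan: MissingnessPlan = field(default_factory=MissingnessPlan)

    def with_seed(self, seed: int) -> "FixtureConfig":
        return replace(self, seed=seed)


def implied_mvn_correlation(config: FixtureConfig, schema: CohortSchema) -> np.ndarray:
    """The correlation matrix the config implies over the schema's mvn
    columns (schema order), PSD-repaired.

    Raises if the implied matrix is materially non-PSD (eigenvalue below
    -1e-6), i.e. the configured cross-trait matrix and decays are mutually
    inconsistent.
    """
    cols = [schema.find(c) for c in schema.mvn_columns]
    k = len(cols)
    C = config.cross_trait_corr
    rho = config.within_trait_corr
    ages = {w.id: w.nominal_age_years for w in schema.waves}
    mat = np.empty((k, k))
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            decay = np.sqrt(rho[ci.kind] * rho[cj.kind]) ** abs(
                ages[ci.wave] - ages[cj.wave]
            )
            mat[i, j] = float(C.loc[ci.kind, cj.kind]) * decay
    np.fill_diagonal(mat, 1.0)
    min_eig = float(np.linalg.eigvalsh(mat).min())
    if min_eig < -1e-6:
        raise ValueError(
            f"implied mvn correlation is not PSD (min eigenvalue {min_eig:.3g}); "
            "adjust cross_trait_corr / within_trait_corr"
        )
    return repair_correlation(mat)


def generate_source_cohort(config: FixtureConfig, schema: CohortSchema) -> pd.DataFrame:
    """Generate the complete (pre-missingness) source cohort.

    Columns follow the schema order; ages are in months (the clinic
    recording convention); sex is 1/2-coded with the configured female
    proportion. Deterministic given ``config.seed``.
    """
    corr = implied_mvn_correlation(config, schema)
    n = config.n
    rng = np.random.default_rng([config.seed, 0])

    sex01 = (rng.random(n) < config.sex_proportion_female).astype(int)

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    z = rng.standard_normal(size=(n, len(corr))) @ chol.T

    data: dict[str, np.ndarray] = {schema.sex_column: (sex01 + 1).astype(np.int64)}
    for j, name in enumerate(schema.mvn_columns):
        spec = schema.find(name)
        mean, sd = config.trait_trajectories[spec.kind][spec.wave]
        shift = config.sex_effects.get(spec.kind, {}).get(spec.wave, 0.0)
        data[name] = mean + sd * z[:, j] + shift * sex01

    for spec in schema.columns_of_role("independent_age"):
        nominal = schema.wave(spec.wave).nominal_age_years
        mean_months = (nominal + config.age_attendance_lag_years) * 12.0
        sd_months = config.age_jitter_sd * 12.0
        data[spec.column_name] = rng.normal(mean_months, sd_months, size=n)

    for spec in schema.columns_of_role("derived_bmi"):
        w = data[schema.same_wave_column(spec.wave, "weight")]
        h = data[schema.same_wave_column(spec.wave, "height")]
        data[spec.column_name] = w / (h / 100.0) ** 2

    return pd.DataFrame(data)[schema.column_names]


def apply_missingness(table: pd.DataFrame, config: FixtureConfig,
                      schema: CohortSchema) -> pd.DataFrame:
    """Introduce missing values wave by wave.

    A deterministic completion mask of ``n_complete_target`` rows is left
    untouched. Every other row misses each clinic wave independently with
    probability ``1 - attendance[wave]`` (all of that wave's columns become
    NA); a row that would end up complete anyway gets one forced NA so the
    complete-case count equals the mask size exactly. Sex is never missing.
    """
    plan = config.missingness_plan
    n = len(table)
    if plan.n_complete_target > n:
        raise ValueError(
            f"n_complete_target ({plan.n_complete_target}) exceeds table size ({n})"
        )
    rng = np.random.default_rng([config.seed, 1])
    mask_rows = np.zeros(n, dtype=bool)
    if plan.n_complete_target > 0:
        keep = rng.permutation(n)[: plan.n_complete_target]
        mask_rows[keep] = True

    out = table.copy()
    float_cols = [c for c in schema.column_names if c != schema.sex_column]
    out[float_cols] = out[float_cols].astype(float)

    wave_columns = {
        w.id: [c.column_name for c in schema.columns if c.wave == w.id]
        for w in schema.waves
    }
    incomplete = ~mask_rows
    any_na = np.zeros(n, dtype=bool)
    for wave_id, cols in wave_columns.items():
        if not cols:
            continue
        p_attend = plan.attendance.get(wave_id, 1.0)
        missed = incomplete & (rng.random(n) >= p_attend)
        if missed.any():
            out.loc[missed, cols] = np.nan
            any_na |= missed

    # force one NA into incomplete rows that attended every clinic
    force = incomplete & ~any_na
    if force.any():
        idx = np.flatnonzero(force)
        choices = rng.integers(0, len(float_cols), size=len(idx))
        col_pos = {c: out.columns.get_loc(c) for c in float_cols}
        for row, ci in zip(idx, choices):
            out.iat[row, col_pos[float_cols[ci]]] = np.nan
    return out


def default_source(seed: int = 2017, n: int | None = None) -> tuple[pd.DataFrame, FixtureConfig]:
    """Convenience: default-configured source cohort with missingness applied.

    Returns the table together with the config used. The schema is the
    bundled one.
    """
    from .schema import load_schema

    config = FixtureConfig(seed=seed)
    if n is not None:
        config = replace(config, n=n)
    schema = load_schema("bundled")
    full = generate_source_cohort(config, schema)
    return apply_missingness(full, config, schema), config
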