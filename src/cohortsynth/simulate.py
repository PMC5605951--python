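"""Synthetic cohort generation.

The generation procedure, per output table of ``n`` rows:

1. draw an ``n x k`` standard-normal block ``Z`` with the estimated
   correlation structure (Cholesky factor of the repaired matrix; eigen
   fallback);
2. rescale each column to its source mean and SD by the inverse z-score
   transform ``X = Z·σ + µ``;
3. draw each clinic's exact-age column independently from a normal with the
   source mean and variance (years);
4. compute BMI from the simulated same-wave weight and height,
   ``BMI = weight / (height/100)²`` -- never drawn independently;
5. compute each row's sex from the fitted logistic model applied to the
   synthetic continuous columns: log odds -> expit -> Bernoulli, with 0
   mapped back to code 1 (male) and 1 to code 2 (female).

No truncation is applied to physiologically impossible tail draws (negative
weights etc.); the generator only logs how many values fall below zero.
A single master seed drives everything via fixed per-stage offsets (MVN
block = seed, sex = seed + 1, age column i = seed + 10 + i), so stages are
reproducible in isolation.
"""

from __future__ import annotations

import logging
from typing import Sequence, Union
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.csv as pacsv
from scipy.special import expit as _sp_expit

from .preprocess import ColumnMoments, SexModel, SimulationParams
from .schema import CohortSchema

logger = logging.getLogger(__name__)

__all__ = [
    "draw_mvn_block",
    "destandardize",
    "expit",
    "simulate_sex",
    "derive_bmi",
    "simulate_age",
    "simulate_dataset",
    "write_csv",
]

SEX_SEED_OFFSET = 1
AGE_SEED_OFFSET = 10


def draw_mvn_block(n: int, correlation: np.ndarray, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. rows from N(0, correlation).

    The matrix must already be positive semi-definite (see
    :func:`cohortsynth.preprocess.repair_correlation`); factorisation is by
    Cholesky, falling back to an eigendecomposition square root if the
    matrix is PSD but numerically rank-deficient. Deterministic given
    ``(n, correlation, seed)``.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    corr = np.asarray(correlation, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    try:
        factor = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(corr)
        if eigval.min() < -1e-8:
            raise ValueError(
                "correlation matrix is not positive semi-definite; repair it first"
            ) from None
        factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n, corr.shape[0]))
    z = z @ factor.T
    return z


def destandardize(Z: Sequence[float], m: ColumnMoments) -> np.ndarray:
    """Inverse z-score transform X = Z·σ + µ."""
    return np.asarray(Z, dtype=float) * m.sigma + m.mu


def expit(y):
    """Inverse logit p = exp(y) / (1 + exp(y)), overflow-safe."""
    return _sp_expit(np.asarray(y, dtype=float))


def simulate_sex(
    continuous_columns: pd.DataFrame, model: SexModel, seed: int
) -> np.ndarray:
    """Simulate the 1/2-coded sex column from the fitted logistic model.

    Per row: log odds from the linear predictor, probability by expit, a
    Bernoulli draw, then 0 -> 1 (male) and 1 -> 2 (female).
    """
    p = model.predict_proba(continuous_columns)
    rng = np.random.default_rng(seed)
    draw = rng.random(len(p)) < p
    return np.where(draw, 2, 1).astype(np.int64)


def derive_bmi(weight: Sequence[float], height: Sequence[float]) -> np.ndarray:
    """BMI (kg/m²) = weight / (height/100)², with height in cm."""
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(h == 0):
        raise ValueError("height contains zero; BMI is undefined")
    return w / (h / 100.0) ** 2


def simulate_age(n: int, mean_years: float, variance_years2: float, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. ages (years) ~ N(mean, variance), independent of
    every other column."""
    if variance_years2 <= 0:
        raise ValueError(f"age variance must be positive, got {variance_years2}")
    rng = np.random.default_rng(seed)
    return rng.normal(mean_years, np.sqrt(variance_years2), size=n)


def simulate_dataset(
    params: SimulationParams,
    schema: CohortSchema,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a complete synthetic cohort of ``n`` rows in schema order.

    The returned frame carries provenance (seed, n, parameter fingerprint)
    in ``DataFrame.attrs``.
    """
    if set(params.mvn_columns) != set(schema.mvn_columns):
        raise ValueError("params and schema disagree on the mvn column set")
    if set(params.age_moments) != set(schema.age_columns):
        raise ValueError("params and schema disagree on the age column set")

    z = draw_mvn_block(n, params.correlation, seed)
    data: dict[str, np.ndarray] = {}
    for j, col in enumerate(params.mvn_columns):
        data[col] = destandardize(z[:, j], params.moments[col])
    del z

    for i, col in enumerate(schema.age_columns):
        mean_y, var_y2 = params.age_moments[col]
        data[col] = simulate_age(n, mean_y, var_y2, seed + AGE_SEED_OFFSET + i)

    for col in schema.bmi_columns:
        spec = schema.find(col)
        w = data[schema.same_wave_column(spec.wave, "weight")]
        h = data[schema.same_wave_column(spec.wave, "height")]
        data[col] = derive_bmi(w, h)

    table = pd.DataFrame(data)
    sex = simulate_sex(
        table[list(params.sex_model.coefficients)],
        params.sex_model,
        seed + SEX_SEED_OFFSET,
    )
    table[schema.sex_column] = sex
    table = table[schema.column_names]

    negative = int(sum((data[c] < 0).sum() for c in schema.continuous_columns))
    if negative:
        logger.warning(
            "%d simulated values fall below 0 across %d rows (untruncated "
            "Gaussian tails)",
            negative,
            n,
        )

    table.attrs["provenance"] = {
        "seed": seed,
        "n": n,
        "params_fingerprint": params.fingerprint(),
    }
    return table


def write_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a synthetic table as CSV: header verbatim, no row index, full
    round-trip double precision, LF line endings."""
    arrow = pa.Table.from_pandas(table, preserve_index=False)
    pacsv.write_csv(arrow, str(path))
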