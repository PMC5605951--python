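"""Source-table cleaning and parameter estimation.

The simulator needs five things from a source cohort, all estimated here on
the complete cases (rows with no missing value in any schema column):

* per-column means and standard deviations of the continuous measurement
  ("mvn") block, used for z-score standardisation and its inverse;
* the correlation matrix of that block (equivalently, the covariance of the
  standardised block), repaired to be positive semi-definite so a Cholesky
  factor exists;
* a logistic model for sex (recoded 1/2 -> 0/1) regressed on the continuous
  columns, fitted by iteratively reweighted least squares with a small
  ridge penalty on the slopes -- the design is near-collinear because BMI
  is a deterministic function of height and weight;
* per-clinic age means and variances on the year scale (source ages are
  recorded in months and divided by 12 once, here);
* the sex proportion and the complete-case count.

Sample statistics use the n-1 denominator throughout, matching the
``mean()`` / ``sd()`` / ``cov()`` conventions of the reference environment
the generation procedure was originally scripted in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit as _expit

from .schema import CohortSchema

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMoments",
    "SexModel",
    "SimulationParams",
    "EstimationError",
    "DegenerateColumnError",
    "SeparationError",
    "read_source_csv",
    "complete_cases",
    "ages_months_to_years",
    "standardize",
    "repair_correlation",
    "fit_sex_model",
    "estimate_params",
]

#: smallest eigenvalue tolerated before the correlation matrix is repaired
PSD_EIG_FLOOR = 1e-10


class EstimationError(ValueError):
    """Estimation cannot proceed (too few rows, bad coding, ...)."""


class DegenerateColumnError(EstimationError):
    """A column is constant (zero standard deviation)."""


class SeparationError(EstimationError):
    """The logistic fit diverged (complete or quasi-complete separation)."""


@dataclass(frozen=True)
class ColumnMoments:
    """Mean µ and standard deviation σ of one column, in original units."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise DegenerateColumnError("non-finite moments")
        if self.sigma <= 0:
            raise DegenerateColumnError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class SexModel:
    """Fitted logistic model for sex: P(female) = expit(a + x·b).

    Source coding 1 (male) / 2 (female) is mapped to 0 / 1, so the
    modelled probability is the probability of being female.
    """

    intercept: float
    coefficients: dict[str, float]  # keyed by predictor column name
    coding: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 1})

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        missing = [k for k in self.coefficients if k not in table.columns]
        if missing:
            raise KeyError(f"predictor columns missing from table: {missing}")
        keys = list(self.coefficients)
        beta = np.array([self.coefficients[k] for k in keys])
        return self.intercept + table[keys].to_numpy(dtype=float) @ beta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return _expit(self.linear_predictor(table))


@dataclass
class SimulationParams:
    """Everything the generator needs, as estimated from a source table."""

    moments: dict[str, ColumnMoments]  # one entry per mvn column
    mvn_columns: list[str]  # order of the correlation matrix
    correlation: np.ndarray  # PSD-repaired, unit diagonal
    sex_model: SexModel
    sex_proportion: float  # fraction coded 2 (female)
    age_moments: dict[str, tuple[float, float]]  # column -> (mean y, var y²)
    n_complete: int

    def fingerprint(self) -> str:
        """Short stable hash of the parameter values, for provenance."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.correlation).tobytes())
        for name in self.mvn_columns:
            m = self.moments[name]
            h.update(f"{name}:{m.mu!r}:{m.sigma!r};".encode())
        h.update(repr(sorted(self.sex_model.coefficients.items())).encode())
        h.update(repr(self.sex_model.intercept).encode())
        h.update(repr(sorted(self.age_moments.items())).encode())
        h.update(repr(self.sex_proportion).encode())
        return h.hexdigest()[:16]

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_complete": self.n_complete,
            "sex_proportion": self.sex_proportion,
            "mvn_columns": list(self.mvn_columns),
            "moments": {
                k: {"mu": m.mu, "sigma": m.sigma} for k, m in self.moments.items()
            },
            "correlation": self.correlation.tolist(),
            "sex_model": {
                "intercept": self.sex_model.intercept,
                "coefficients": dict(self.sex_model.coefficients),
            },
            "age_moments": {
                k: {"mean": mu, "variance": var}
                for k, (mu, var) in self.age_moments.items()
            },
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationParams":
        return cls(
            moments={
                k: ColumnMoments(mu=v["mu"], sigma=v["sigma"])
                for k, v in raw["moments"].items()
            },
            mvn_columns=list(raw["mvn_columns"]),
            correlation=np.asarray(raw["correlation"], dtype=float),
            sex_model=SexModel(
                intercept=float(raw["sex_model"]["intercept"]),
                coefficients={
                    k: float(v) for k, v in raw["sex_model"]["coefficients"].items()
                },
            ),
            sex_proportion=float(raw["sex_proportion"]),
            age_moments={
                k: (float(v["mean"]), float(v["variance"]))
                for k, v in raw["age_moments"].items()
            },
            n_complete=int(raw["n_complete"]),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SimulationParams":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# cleaning


def read_source_csv(path: Union[str, Path], schema: CohortSchema | None = None) -> pd.DataFrame:
    """Read a source cohort CSV (header row, "NA" marks missing values)."""
    table = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    if schema is not None:
        missing = [c for c in schema.column_names if c not in table.columns]
        if missing:
            raise EstimationError(f"source table lacks schema columns: {missing}")
    return table


def complete_cases(table: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    """Drop every row with a missing value in any schema column.

    Row order is preserved; columns are restricted to the schema, in schema
    order.
    """
    missing = [c for c in schema.column_names if c not in table.columns]
    if missing:
        raise EstimationError(f"source table lacks schema columns: {missing}")
    sub = table[schema.column_names]
    clean = sub.dropna(axis=0, how="any")
    if len(clean) == 0:
        raise EstimationError(
            "no complete cases remain after removing rows with missing values; "
            "parameter estimation is impossible"
        )
    return clean


def ages_months_to_years(table: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    """Return a copy with each age column divided by 12 (months -> years)."""
    out = table.copy()
    for col in schema.age_columns:
        out[col] = out[col] / 12.0
    return out


# ---------------------------------------------------------------------------
# standardisation


def standardize(x: Sequence[float], m: ColumnMoments) -> np.ndarray:
    """z-score transform z = (x - µ) / σ."""
    if m.sigma <= 0:
        raise DegenerateColumnError(f"sigma must be > 0, got {m.sigma}")
    return (np.asarray(x, dtype=float) - m.mu) / m.sigma


# ---------------------------------------------------------------------------
# correlation estimation and PSD repair


def repair_correlation(corr: np.ndarray, eig_floor: float = PSD_EIG_FLOOR) -> np.ndarray:
    """Clip eigenvalues below ``eig_floor``, rebuild, rescale diagonal to 1.

    Empirical correlation matrices of near-collinear longitudinal blocks can
    be numerically indefinite; the repaired matrix admits a Cholesky
    factorisation. Matrices already PSD are returned unchanged (symmetrised).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    sym = (corr + corr.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() >= eig_floor:
        return sym
    clipped = np.maximum(eigval, eig_floor)
    rebuilt = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(rebuilt))
    rebuilt = rebuilt / np.outer(d, d)
    np.fill_diagonal(rebuilt, 1.0)
    return (rebuilt + rebuilt.T) / 2.0


def _column_moments(clean: pd.DataFrame, columns: Sequence[str]) -> dict[str, ColumnMoments]:
    out = {}
    for col in columns:
        x = clean[col].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sigma = float(np.std(x, ddof=1))
        if sigma <= 0 or not np.isfinite(sigma):
            raise DegenerateColumnError(f"column {col!r} is constant (sd = {sigma})")
        out[col] = ColumnMoments(mu=mu, sigma=sigma)
    return out


# ---------------------------------------------------------------------------
# logistic fit (IRLS with ridge stabiliser)


def fit_sex_model(
    predictors: pd.DataFrame,
    sex01: Sequence[int],
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SexModel:
    """Fit the logistic model sex01 ~ predictors by penalised IRLS.

    A ridge penalty ``ridge`` (default 1e-6) on the slopes -- never the
    intercept -- keeps the Newton steps solvable when the design is
    near-collinear. Convergence is declared when the largest absolute
    coefficient update drops below ``tol``; each step is halved until the
    penalised deviance does not increase.
    """
    y = np.asarray(sex01, dtype=float)
    bad = set(np.unique(y)) - {0.0, 1.0}
    if bad:
        raise EstimationError(f"sex01 must be 0/1 coded, found values {sorted(bad)}")
    if y.min() == y.max():
        raise EstimationError(
            "response is constant (all 0 or all 1); a logistic model cannot be fitted"
        )
    X = np.column_stack(
        [np.ones(len(y))] + [predictors[c].to_numpy(dtype=float) for c in predictors.columns]
    )
    n, p = X.shape
    penalty = np.full(p, ridge)
    penalty[0] = 0.0  # intercept unpenalised

    def penalized_deviance(beta: np.ndarray) -> float:
        eta = X @ beta
        # log(1 + e^eta) computed stably
        ll = y * eta - np.logaddexp(0.0, eta)
        return -2.0 * ll.sum() + penalty @ beta**2

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))  # null-model start
    dev = penalized_deviance(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - penalty * beta
        H = (X.T * w) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        # step-halving keeps the penalised deviance non-increasing
        scale = 1.0
        for _halving in range(30):
            candidate = beta + scale * step
            cand_dev = penalized_deviance(candidate)
            if cand_dev <= dev + 1e-12:
                break
            scale /= 2.0
        beta_new = beta + scale * step
        delta = np.max(np.abs(beta_new - beta))
        beta, dev = beta_new, penalized_deviance(beta_new)
        if delta < tol:
            converged = True
            break
    slopes = beta[1:]
    # complete separation: the unpenalised MLE does not exist, the ridge
    # alone decides the coefficient scale -- refuse rather than return it
    margins = (2.0 * y - 1.0) * (X @ beta)
    if (
        np.max(np.abs(slopes), initial=0.0) > 1e3
        or not np.isfinite(dev)
        or bool(np.all(margins > 0.0))
    ):
        raise SeparationError(
            "the data are completely separated: logistic coefficients are "
            "determined only by the ridge stabiliser; use a larger stabiliser "
            "or fewer predictors"
        )
    if not converged:
        logger.warning("sex-model IRLS stopped at max_iter without full convergence")
    return SexModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(predictors.columns, slopes)},
    )


# ---------------------------------------------------------------------------
# the estimator


def estimate_params(
    clean: pd.DataFrame,
    schema: CohortSchema,
    sex_predictors: Literal["all_continuous", "mvn_only"] = "all_continuous",
    ridge: float = 1e-6,
    ages_in: Literal["months", "years"] = "months",
) -> SimulationParams:
    """Estimate every simulation parameter from a complete-case table.

    ``sex_predictors`` selects the design of the logistic sex model: every
    continuous column (measurements, BMI and age -- the default) or the
    measurement block only. ``ages_in`` declares the unit of the source age
    columns; months (the clinic recording convention) are converted to years
    before any moment is taken.
    """
    if clean[schema.column_names].isna().any().any():
        raise EstimationError("estimate_params requires a complete-case table")
    n = len(clean)
    mvn_cols = schema.mvn_columns
    if n < len(mvn_cols) + 2:
        raise EstimationError(
            f"{n} complete cases are too few to estimate a {len(mvn_cols)}-column "
            f"correlation matrix (need at least {len(mvn_cols) + 2})"
        )

    sex_raw = clean[schema.sex_column].to_numpy()
    levels = set(np.unique(sex_raw).tolist())
    if not levels <= {1, 2, 1.0, 2.0}:
        raise EstimationError(
            f"sex column must be coded 1 (male) / 2 (female); found {sorted(levels)}"
        )
    sex01 = (np.asarray(sex_raw, dtype=float) - 1.0).astype(int)

    if ages_in == "months":
        clean = ages_months_to_years(clean, schema)

    moments = _column_moments(clean, mvn_cols)

    # covariance of the standardised block == correlation of the raw block
    z = np.column_stack(
        [standardize(clean[c].to_numpy(dtype=float), moments[c]) for c in mvn_cols]
    )
    corr = (z.T @ z) / (n - 1)
    corr = repair_correlation(corr)

    age_moments = {}
    for col in schema.age_columns:
        a = clean[col].to_numpy(dtype=float)
        var = float(np.var(a, ddof=1))
        if var <= 0:
            raise DegenerateColumnError(f"age column {col!r} is constant")
        age_moments[col] = (float(np.mean(a)), var)

    predictor_cols = (
        schema.continuous_columns if sex_predictors == "all_continuous" else mvn_cols
    )
    sex_model = fit_sex_model(clean[predictor_cols], sex01, ridge=ridge)

    return SimulationParams(
        moments=moments,
        mvn_columns=list(mvn_cols),
        correlation=corr,
        sex_model=sex_model,
        sex_proportion=float(sex01.mean()),
        age_moments=age_moments,
        n_complete=n,
    )
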