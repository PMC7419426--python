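"""Log-linear determinants-of-exposure model for RCS concentrations.

The model is an ordinary least squares regression of ln(concentration) on
categorical determinants — the Common Silica Process (task/material/tool),
industry sector, project type, work environment, geographic region — a
continuous sampling-duration term, and indicator terms for engineering
controls (local exhaust ventilation, LEV integrated with tool, material
wetting, water-spray integrated with tool). Exposure data are lognormal and
non-detects are imputed multiplicatively (½ LOD), so the log scale is the
natural one; exponentiating the linear predictor gives a geometric-mean
concentration in mg/m³.

Separation from source (e.g. an enclosed cab) is deliberately *not* a
regression term: there are rarely enough measurements behind it to fit, so
its effect is applied post-hoc as a fixed literature-derived reduction
factor (see :mod:`silicarisk.predict`).

The fitted object is exposed two ways:

* :class:`SilicaExposureRegressor` — a scikit-learn estimator
  (``fit``/``predict``/``get_params``) over a pandas DataFrame of
  determinants, composable with sklearn model selection;
* :class:`ExposureModel` — the serializable coefficient/SE document the
  prediction and ECP layers consume, version-stamped with the database
  release it was fitted from.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    RankDeficiencyError,
    SchemaVersionError,
    UnknownLevelError,
)
from .measurements import ExposureMeasurement

MODEL_SCHEMA_VERSION = "1"

#: Engineering controls with coefficients fitted from data.
FITTED_CONTROLS = ("LEV", "LEV_integrated", "wetting", "waterspray_integrated")
#: Separation from source is credited post-hoc, never fitted.
SEPARATION_CONTROL = "separation"
CONTROL_IDS = frozenset(FITTED_CONTROLS) | {SEPARATION_CONTROL}

DEFAULT_CATEGORICALS = ("csp_id", "sector", "project_type", "environment", "region")

INTERCEPT = "Intercept"
LOG_DURATION = "log_duration"
LINEAR_DURATION = "duration"


@dataclass(frozen=True)
class Scenario:
    """A user-described task: what will be done, where, and with what controls."""

    csp_id: str
    sector: str
    project_type: str
    environment: str
    region: str
    sampling_duration: float = 480.0  # minutes
    task_duration_hours: float = 8.0
    controls: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "controls", frozenset(self.controls))
        if self.sampling_duration <= 0:
            raise InvalidInputError(
                f"sampling_duration must be positive, got {self.sampling_duration}"
            )
        if self.task_duration_hours <= 0:
            raise InvalidInputError(
                f"task_duration_hours must be positive, got {self.task_duration_hours}"
            )
        unknown = self.controls - CONTROL_IDS
        if unknown:
            raise InvalidInputError(
                f"unknown control identifier(s) {sorted(unknown)}; "
                f"valid controls are {sorted(CONTROL_IDS)}"
            )

    def without_controls(self) -> "Scenario":
        return replace(self, controls=frozenset())


@dataclass(frozen=True)
class ExposureModel:
    """Fitted coefficient/SE table with reference levels and version stamp.

    ``coefficients`` maps each term of ``term_catalog`` to
    (estimate, standard error) on the log-mg/m³ scale. Every categorical
    variable has exactly one reference level, absent from the catalog.
    ``covariance`` optionally carries the full coefficient covariance
    matrix (row order = term_catalog); by default only the marginal SEs
    are stored, matching how the Monte Carlo step draws coefficients.
    """

    coefficients: dict[str, tuple[float, float]]
    reference_levels: dict[str, str]
    residual_log_sd: float
    db_version: str
    fit_n: int
    term_catalog: tuple[str, ...]
    duration_term: Optional[str] = LOG_DURATION  # "log_duration" | "duration" | None
    covariance: Optional[tuple[tuple[float, ...], ...]] = None

    def __post_init__(self):
        if tuple(self.coefficients) != tuple(self.term_catalog):
            raise InvalidInputError("coefficients must be keyed in term_catalog order")
        for term, (_, se) in self.coefficients.items():
            if se < 0:
                raise InvalidInputError(f"negative SE for term {term!r}")
        if self.fit_n <= len(self.term_catalog):
            raise InvalidInputError(
                f"fit_n={self.fit_n} must exceed the number of terms "
                f"({len(self.term_catalog)})"
            )

    @property
    def estimates(self) -> np.ndarray:
        return np.array([est for est, _ in self.coefficients.values()])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([se for _, se in self.coefficients.values()])

    def levels(self, variable: str) -> set[str]:
        """All known levels of a categorical variable, including the reference."""
        prefix = variable + "="
        found = {t[len(prefix):] for t in self.term_catalog if t.startswith(prefix)}
        found.add(self.reference_levels[variable])
        return found


# ---------------------------------------------------------------------------
# design matrix construction


def records_to_frame(records: Iterable[ExposureMeasurement]) -> pd.DataFrame:
    """Tabulate measurement records into the modeling DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "concentration": r.concentration,
                "duration": r.duration,
                "csp_id": r.csp_id,
                "sector": r.sector,
                "project_type": r.project_type,
                "environment": r.environment,
                "region": r.region,
                "controls": set(r.controls),
                "weight": r.weight,
            }
        )
    return pd.DataFrame(rows)


def _row_controls(value) -> set[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return set()
    if isinstance(value, str):
        return {c for c in (s.strip() for s in value.split(";")) if c}
    return set(value)


def _duration_column(df: pd.DataFrame, duration_term: Optional[str]) -> Optional[np.ndarray]:
    if duration_term is None:
        return None
    d = df["duration"].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise InvalidInputError("durations must be positive")
    return np.log(d) if duration_term == LOG_DURATION else d


def build_design(
    df: pd.DataFrame,
    categoricals: Sequence[str],
    duration_term: Optional[str],
    controls: Sequence[str],
    reference_levels: dict[str, str],
    levels: dict[str, list[str]],
) -> tuple[np.ndarray, list[str]]:
    """One-hot design matrix over a fixed term catalog.

    ``levels`` lists non-reference levels per variable (catalog order).
    Rows with a level outside the catalog raise :class:`UnknownLevelError`.
    """
    n = len(df)
    columns: list[str] = [INTERCEPT]
    blocks: list[np.ndarray] = [np.ones((n, 1))]

    dur = _duration_column(df, duration_term)
    if dur is not None:
        columns.append(duration_term)
        blocks.append(dur.reshape(-1, 1))

    for var in categoricals:
        known = set(levels[var]) | {reference_levels[var]}
        observed = df[var].astype(str)
        bad = set(observed) - known
        if bad:
            raise UnknownLevelError(var, sorted(bad)[0])
        for lev in levels[var]:
            columns.append(f"{var}={lev}")
            blocks.append((observed == lev).to_numpy(dtype=float).reshape(-1, 1))

    row_controls = [_row_controls(v) for v in df["controls"]] if "controls" in df else [set()] * n
    for ctl in controls:
        columns.append(f"control={ctl}")
        blocks.append(
            np.array([1.0 if ctl in s else 0.0 for s in row_controls]).reshape(-1, 1)
        )

    return np.hstack(blocks), columns


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted(columns[i] for i in piv[rank:])
        raise RankDeficiencyError(aliased)


# ---------------------------------------------------------------------------
# estimator


class SilicaExposureRegressor(RegressorMixin, BaseEstimator):
    """OLS on ln(concentration) over categorical determinants and controls.

    Parameters
    ----------
    categoricals : sequence of str
        Categorical determinants to encode (default: CSP, sector,
        project type, environment, region).
    duration_term : {"log_duration", "duration", None}
        Continuous sampling-duration term; the default models log-minutes.
    controls : sequence of str
        Engineering-control indicators to fit; only controls observed in the
        data are kept. Separation from source is always excluded (post-hoc).
    reference_levels : dict or None
        Reference level per categorical; default is the alphabetically
        first observed level (deterministic).
    min_cell_count : int
        Fitting refuses a categorical level with fewer observations
        (default 5); counts below ``warn_cell_count`` (10) warn.
    db_version : str
        Version stamp recorded in the fitted model document.
    store_covariance : bool
        Also keep the full coefficient covariance matrix.

    Attributes
    ----------
    model_ : ExposureModel
        The serializable fitted document.
    coef_, se_ : ndarray
        Estimates and standard errors, term-catalog order.
    term_catalog_ : list of str
    reference_levels_ : dict
    residual_log_sd_ : float
    """

    def __init__(
        self,
        categoricals: Sequence[str] = DEFAULT_CATEGORICALS,
        duration_term: Optional[str] = LOG_DURATION,
        controls: Sequence[str] = FITTED_CONTROLS,
        reference_levels: Optional[dict[str, str]] = None,
        min_cell_count: int = 5,
        warn_cell_count: int = 10,
        db_version: str = "unversioned",
        store_covariance: bool = False,
    ):
        self.categoricals = categoricals
        self.duration_term = duration_term
        self.controls = controls
        self.reference_levels = reference_levels
        self.min_cell_count = min_cell_count
        self.warn_cell_count = warn_cell_count
        self.db_version = db_version
        self.store_covariance = store_covariance

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Optional[np.ndarray] = None):
        """Fit on a DataFrame of determinants.

        ``y`` is the concentration vector in mg/m³; if omitted, the
        DataFrame's ``concentration`` column is used.
        """
        df = X.reset_index(drop=True)
        if y is None:
            if "concentration" not in df:
                raise InvalidInputError(
                    "y not given and no 'concentration' column in X"
                )
            y = df["concentration"].to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise InvalidInputError(
                "concentrations must be positive (substitute non-detects first)"
            )
        if len(y) != len(df):
            raise InvalidInputError("X and y length mismatch")

        if SEPARATION_CONTROL in self.controls:
            raise InvalidInputError(
                "separation from source cannot be a fitted term; "
                "it is applied post-hoc"
            )

        refs, levels = self._resolve_levels(df)
        fitted_controls = self._observed_controls(df)

        Xd, columns = build_design(
            df, self.categoricals, self.duration_term, fitted_controls, refs, levels
        )
        if len(y) <= len(columns):
            raise InsufficientDataError(
                "(all)", "(all)", len(y), len(columns) + 1
            )
        _check_rank(Xd, columns)

        w = df["weight"].to_numpy(dtype=float) if "weight" in df else np.ones(len(y))
        res = sm.WLS(np.log(y), Xd, weights=w).fit()

        coeffs = {
            col: (float(res.params[i]), float(res.bse[i]))
            for i, col in enumerate(columns)
        }
        cov = None
        if self.store_covariance:
            cov = tuple(tuple(float(v) for v in row) for row in res.cov_params())
        self.model_ = ExposureModel(
            coefficients=coeffs,
            reference_levels=refs,
            residual_log_sd=float(np.sqrt(res.scale)),
            db_version=self.db_version,
            fit_n=int(len(y)),
            term_catalog=tuple(columns),
            duration_term=self.duration_term,
            covariance=cov,
        )
        self.coef_ = self.model_.estimates
        self.se_ = self.model_.standard_errors
        self.term_catalog_ = list(columns)
        self.reference_levels_ = dict(refs)
        self.residual_log_sd_ = self.model_.residual_log_sd
        self.n_features_in_ = df.shape[1]
        return self

    def _resolve_levels(self, df: pd.DataFrame):
        refs: dict[str, str] = {}
        levels: dict[str, list[str]] = {}
        for var in self.categoricals:
            if var not in df:
                raise InvalidInputError(f"missing determinant column {var!r}")
            counts = df[var].astype(str).value_counts()
            for lev, cnt in counts.items():
                if cnt < self.min_cell_count:
                    raise InsufficientDataError(var, lev, int(cnt), self.min_cell_count)
                if cnt < self.warn_cell_count:
                    warnings.warn(
                        f"level {lev!r} of {var!r} has only {cnt} observations",
                        stacklevel=2,
                    )
            observed = sorted(counts.index)
            ref = (self.reference_levels or {}).get(var, observed[0])
            if ref not in observed:
                raise UnknownLevelError(var, ref)
            refs[var] = ref
            levels[var] = [l for l in observed if l != ref]
        return refs, levels

    def _observed_controls(self, df: pd.DataFrame) -> list[str]:
        if "controls" not in df:
            return []
        row_controls = [_row_controls(v) for v in df["controls"]]
        kept = []
        for ctl in self.controls:
            cnt = sum(1 for s in row_controls if ctl in s)
            if cnt == 0:
                continue
            if cnt < self.min_cell_count:
                raise InsufficientDataError("controls", ctl, cnt, self.min_cell_count)
            kept.append(ctl)
        return kept

    # -- prediction --------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Point prediction: the geometric-mean concentration exp(xβ̂), mg/m³."""
        return np.exp(self.predict_log(X))

    def predict_log(self, X: pd.DataFrame) -> np.ndarray:
        model = self.model_
        df = X.reset_index(drop=True)
        levels = {
            var: [t.split("=", 1)[1] for t in model.term_catalog
                  if t.startswith(var + "=")]
            for var in self.categoricals
        }
        fitted_controls = [
            t.split("=", 1)[1] for t in model.term_catalog if t.startswith("control=")
        ]
        Xd, _ = build_design(
            df, self.categoricals, model.duration_term, fitted_controls,
            model.reference_levels, levels,
        )
        return Xd @ model.estimates


# ---------------------------------------------------------------------------
# module-level wrappers and (de)serialization


def fit_model(
    records: Iterable[ExposureMeasurement],
    formula_spec: Optional[dict] = None,
    db_version: str = "unversioned",
) -> ExposureModel:
    """Fit the exposure model on QC-passed records; thin estimator wrapper.

    ``formula_spec`` maps :class:`SilicaExposureRegressor` parameter names
    to values (e.g. ``{"min_cell_count": 2, "duration_term": None}``).
    """
    est = SilicaExposureRegressor(db_version=db_version, **(formula_spec or {}))
    est.fit(records_to_frame(list(records)))
    return est.model_


def encode_scenario(scenario: Scenario, model: ExposureModel) -> np.ndarray:
    """Design vector for one scenario over the model's term catalog.

    Reference levels contribute zero. A categorical value or selected
    control absent from the catalog raises :class:`UnknownLevelError` —
    never a silent fall-back to the reference.
    """
    x = np.zeros(len(model.term_catalog))
    index = {t: i for i, t in enumerate(model.term_catalog)}
    x[index[INTERCEPT]] = 1.0

    if model.duration_term is not None:
        val = scenario.sampling_duration
        x[index[model.duration_term]] = (
            math.log(val) if model.duration_term == LOG_DURATION else val
        )

    for var in model.reference_levels:
        level = getattr(scenario, var)
        if level == model.reference_levels[var]:
            continue
        term = f"{var}={level}"
        if term not in index:
            raise UnknownLevelError(var, level)
        x[index[term]] = 1.0

    for ctl in scenario.controls:
        if ctl == SEPARATION_CONTROL:
            continue  # credited post-hoc in the prediction layer
        term = f"control={ctl}"
        if term not in index:
            raise UnknownLevelError("controls", ctl)
        x[index[term]] = 1.0

    return x


def serialize_model(model: ExposureModel) -> dict:
    """Lossless JSON-ready document for an :class:`ExposureModel`."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "db_version": model.db_version,
        "fit_n": model.fit_n,
        "duration_term": model.duration_term,
        "term_catalog": list(model.term_catalog),
        "coefficients": {
            t: {"estimate": est, "se": se}
            for t, (est, se) in model.coefficients.items()
        },
        "reference_levels": dict(model.reference_levels),
        "residual_log_sd": model.residual_log_sd,
    }
    if model.covariance is not None:
        doc["covariance"] = [list(row) for row in model.covariance]
    return doc


def deserialize_model(doc: dict) -> ExposureModel:
    if not isinstance(doc, dict) or doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"expected schema_version {MODEL_SCHEMA_VERSION!r}, "
            f"got {doc.get('schema_version') if isinstance(doc, dict) else doc!r}"
        )
    required = (
        "db_version", "fit_n", "term_catalog", "coefficients",
        "reference_levels", "residual_log_sd",
    )
    missing = [k for k in required if k not in doc]
    if missing:
        raise SchemaVersionError(f"model document missing field(s): {missing}")
    catalog = tuple(doc["term_catalog"])
    coeffs = {
        t: (float(doc["coefficients"][t]["estimate"]), float(doc["coefficients"][t]["se"]))
        for t in catalog
    }
    cov = doc.get("covariance")
    return ExposureModel(
        coefficients=coeffs,
        reference_levels=dict(doc["reference_levels"]),
        residual_log_sd=float(doc["residual_log_sd"]),
        db_version=str(doc["db_version"]),
        fit_n=int(doc["fit_n"]),
        term_catalog=catalog,
        duration_term=doc.get("duration_term", LOG_DURATION),
        covariance=tuple(tuple(row) for row in cov) if cov is not None else None,
    )


def save_model(model: ExposureModel, path: Path) -> None:
    Path(path).write_text(json.dumps(serialize_model(model), indent=2), encoding="utf-8")


def load_model(path: Path) -> ExposureModel:
    return deserialize_model(json.loads(Path(path).read_text(encoding="utf-8")))
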