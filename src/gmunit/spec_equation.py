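"""Specification-equation regression for gross motor task difficulty.

A *specification equation* expresses a task's difficulty as a linear
function of theory-derived component measures. Here the components are
the ordinal body-position, movement and support ratings, and the model is

    TaskDifficulty = b0 + b1 * BodyPosition + b2 * Movement + b3 * Support

fit by forward stepwise ordinary least squares against observed item
difficulties on an interval metric. The module provides

* Pearson screening of component-difficulty association,
* variance-inflation-factor (VIF) collinearity diagnosis (flag at >= 10),
* the forward stepwise fit with a full :class:`RegressionReport`,
* prediction, and
* the published three-component equation
  (6.76, 1.23, 1.21, 4.93) that defines the GM reference scale.

Ordinal ratings are treated as numeric integer predictors. This is a
deliberate modelling convention carried through the whole pipeline, with
the standard caveat that the resulting coefficients are per rating step
and rating steps are not themselves interval-scaled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from ._rounding import round_half_away
from .task_schema import ComponentRatings, TaskTable

__all__ = [
    "PREDICTORS",
    "SpecificationEquation",
    "CoefficientRecord",
    "StepRecord",
    "RegressionReport",
    "StepwiseConfig",
    "TaskDifficulty",
    "pearson_r",
    "compute_vif",
    "forward_stepwise_fit",
    "predict_difficulty",
    "predict_table",
    "published_equation",
]

#: Predictor names, in task-table column order.
PREDICTORS = ("body_position", "movement", "support")

#: Caveat attached to every fit report: ratings are ordinal codes, so the
#: per-step coefficients cannot themselves be read on an interval scale.
ORDINAL_PREDICTOR_CAVEAT = (
    "Component ratings are ordinal codes treated as numeric predictors; "
    "coefficient estimates are per rating step and should not be "
    "interpreted on an interval scale."
)


@dataclass(frozen=True)
class SpecificationEquation:
    """Intercept plus one coefficient per component measure.

    ``provenance`` records whether the instance came from a fit
    (``"fitted"``) or is the published reference equation
    (``"published"``).
    """

    intercept: float
    coef_body_position: float
    coef_movement: float
    coef_support: float
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        for name in ("intercept", "coef_body_position", "coef_movement", "coef_support"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "body_position": self.coef_body_position,
            "movement": self.coef_movement,
            "support": self.coef_support,
        }

    def predict(self, ratings: ComponentRatings) -> float:
        """Unrounded predicted difficulty for one rating triple."""
        return (
            self.intercept
            + self.coef_body_position * ratings.body_position
            + self.coef_movement * ratings.movement
            + self.coef_support * ratings.support
        )


class TaskDifficulty(NamedTuple):
    """A predicted difficulty, unrounded and at printed (2 dp) precision."""

    raw: float
    rounded: float


class CoefficientRecord(NamedTuple):
    estimate: float
    se: float
    p_value: float


class StepRecord(NamedTuple):
    """One entry step of the forward stepwise search."""

    predictor: str
    adjusted_r2: float
    partial_f_p: float


@dataclass(frozen=True)
class RegressionReport:
    """Fit statistics of a specification-equation fit."""

    adjusted_r2: float
    f_value: float
    rmse: float
    coefficients: dict[str, CoefficientRecord]
    vif: dict[str, float]
    vif_flagged: dict[str, bool]
    step_trace: tuple[StepRecord, ...]
    pearson_r_predicted_vs_observed: float
    n_obs: int
    caveats: tuple[str, ...] = (ORDINAL_PREDICTOR_CAVEAT,)

    def to_dict(self) -> dict:
        return {
            "adjusted_r2": self.adjusted_r2,
            "f_value": self.f_value,
            "rmse": self.rmse,
            "coefficients": {
                name: {"estimate": rec.estimate, "se": rec.se, "p_value": rec.p_value}
                for name, rec in self.coefficients.items()
            },
            "vif": self.vif,
            "vif_flagged": self.vif_flagged,
            "step_trace": [
                {"predictor": s.predictor, "adjusted_r2": s.adjusted_r2, "partial_f_p": s.partial_f_p}
                for s in self.step_trace
            ],
            "pearson_r_predicted_vs_observed": self.pearson_r_predicted_vs_observed,
            "n_obs": self.n_obs,
            "caveats": list(self.caveats),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable text summary."""
        lines = [
            f"n = {self.n_obs}",
            f"adjusted R^2 = {self.adjusted_r2:.4f}",
            f"F = {self.f_value:.2f}",
            f"RMSE = {self.rmse:.2f}",
            f"r(predicted, observed) = {self.pearson_r_predicted_vs_observed:.2f}",
            "coefficients:",
        ]
        for name, rec in self.coefficients.items():
            vif = self.vif.get(name)
            vif_txt = f", VIF = {vif:.2f}" if vif is not None else ""
            lines.append(
                f"  {name}: beta = {rec.estimate:.2f}, SE = {rec.se:.2f}, "
                f"p = {rec.p_value:.4g}{vif_txt}"
            )
        entered = [s.predictor for s in self.step_trace]
        lines.append(f"entry order: {' -> '.join(entered) if entered else '(intercept only)'}")
        for caveat in self.caveats:
            lines.append(f"note: {caveat}")
        return "\n".join(lines)


@dataclass(frozen=True)
class StepwiseConfig:
    """Settings for the forward stepwise search.

    entry_alpha:
        A candidate is admitted only if its partial-F p-value is below
        this level.
    max_steps:
        Cap on the number of predictors entered (None = no cap).
    vif_threshold:
        Collinearity flag threshold on the variance inflation factor.
    drop_collinear:
        If True, flagged predictors are removed before the search
        (dropping, per flagged pair, the one with the weaker zero-order
        correlation to the outcome). Default False: collinearity is
        reported, never silently acted on.
    """

    entry_alpha: float = 0.05
    max_steps: Optional[int] = None
    vif_threshold: float = 10.0
    drop_collinear: bool = False


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length vectors.

    Raises
    ------
    ValueError
        If the vectors differ in length, have fewer than 3 entries, or
        either is constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def compute_vif(
    predictors: pd.DataFrame | np.ndarray,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Variance inflation factor of each predictor column.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from the OLS regression (with
    intercept) of predictor j on the remaining predictors. An exactly
    collinear predictor gets ``inf``. Returns a DataFrame indexed by
    predictor name with columns ``vif`` and ``flagged`` (VIF >= threshold).
    """
    X = pd.DataFrame(predictors)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors to compute VIFs")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    vifs = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(X[col].to_numpy(dtype=float), others).fit().rsquared
        vifs[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    out = pd.DataFrame({"vif": pd.Series(vifs)})
    out["flagged"] = out["vif"] >= threshold
    return out


def _design(table: TaskTable) -> pd.DataFrame:
    return pd.DataFrame(table.ratings_matrix(), columns=list(PREDICTORS), dtype=float)


def _adjusted_r2(model) -> float:
    r2 = model.rsquared_adj
    return 0.0 if np.isnan(r2) else float(r2)


def forward_stepwise_fit(
    observed_difficulties: Sequence[float],
    table: TaskTable,
    config: StepwiseConfig | None = None,
) -> tuple[SpecificationEquation, RegressionReport]:
    """Fit a specification equation by forward stepwise OLS.

    At each step the remaining candidate giving the largest adjusted-R^2
    increase is tried and admitted iff its partial-F p-value is below
    ``config.entry_alpha``; there is no removal step. Predictors never
    entered carry coefficient 0 in the returned equation.

    Returns the fitted :class:`SpecificationEquation` and a
    :class:`RegressionReport` carrying the step trace, adjusted R^2,
    overall F, RMSE (root mean squared error on n - k - 1 residual
    degrees of freedom), per-coefficient estimates/SEs/p-values, VIFs of
    all three components, and the Pearson correlation between fitted
    predictions and the observed difficulties.
    """
    config = config or StepwiseConfig()
    y = np.asarray(observed_difficulties, dtype=float)
    if y.ndim != 1 or len(y) != len(table):
        raise ValueError("need exactly one observed difficulty per task")
    if len(table) < 10:
        raise ValueError("need at least 10 tasks for a stepwise fit")
    X = _design(table)
    if len(y) < X.shape[1] + 2:
        raise ValueError("degenerate design: too few rows for the candidate predictors")

    vif_table = compute_vif(X, threshold=config.vif_threshold)
    candidates = list(PREDICTORS)
    if config.drop_collinear:
        candidates = _drop_collinear(y, X, candidates, config.vif_threshold)

    entered: list[str] = []
    trace: list[StepRecord] = []
    current = sm.OLS(y, np.ones((len(y), 1))).fit()
    y_constant = np.ptp(y) == 0

    while candidates and (config.max_steps is None or len(entered) < config.max_steps):
        best = None
        for cand in candidates:
            cols = entered + [cand]
            model = sm.OLS(y, sm.add_constant(X[cols].to_numpy())).fit()
            gain = _adjusted_r2(model) - _adjusted_r2(current)
            if best is None or gain > best[1]:
                best = (cand, gain, model)
        cand, _, model = best
        p_new = float(model.pvalues[-1])  # partial F of one added term == its t-test
        if y_constant or not (p_new < config.entry_alpha):
            break
        entered.append(cand)
        candidates.remove(cand)
        current = model
        trace.append(StepRecord(cand, _adjusted_r2(model), p_new))

    if not entered:
        warnings.warn(
            "no predictor met the entry criterion; returning intercept-only model",
            stacklevel=2,
        )

    params = dict(zip(["const"] + entered, np.atleast_1d(current.params)))
    bses = dict(zip(["const"] + entered, np.atleast_1d(current.bse)))
    pvals = dict(zip(["const"] + entered, np.atleast_1d(current.pvalues)))

    equation = SpecificationEquation(
        intercept=float(params["const"]),
        coef_body_position=float(params.get("body_position", 0.0)),
        coef_movement=float(params.get("movement", 0.0)),
        coef_support=float(params.get("support", 0.0)),
        provenance="fitted",
    )
    fitted = np.asarray(current.fittedvalues, dtype=float)
    try:
        r_pred_obs = pearson_r(fitted, y)
    except ValueError:
        r_pred_obs = float("nan")

    coefficients = {
        name: CoefficientRecord(float(params[name]), float(bses[name]), float(pvals[name]))
        for name in ["const"] + entered
    }
    report = RegressionReport(
        adjusted_r2=_adjusted_r2(current),
        f_value=float(current.fvalue) if entered else float("nan"),
        rmse=float(np.sqrt(current.mse_resid)) if entered else float(np.std(y, ddof=1)),
        coefficients=coefficients,
        vif=vif_table["vif"].to_dict(),
        vif_flagged=vif_table["flagged"].to_dict(),
        step_trace=tuple(trace),
        pearson_r_predicted_vs_observed=r_pred_obs,
        n_obs=len(y),
    )
    return equation, report


def _drop_collinear(
    y: np.ndarray, X: pd.DataFrame, candidates: list[str], threshold: float
) -> list[str]:
    """Iteratively drop the flagged predictor least correlated with y."""
    candidates = list(candidates)
    while len(candidates) >= 2:
        vifs = compute_vif(X[candidates], threshold=threshold)
        flagged = [c for c in candidates if vifs.loc[c, "flagged"]]
        if not flagged:
            break
        weakest = min(flagged, key=lambda c: abs(pearson_r(X[c].to_numpy(), y)))
        warnings.warn(f"dropping collinear predictor {weakest!r} (VIF >= {threshold})", stacklevel=3)
        candidates.remove(weakest)
    return candidates


def predict_difficulty(
    equation: SpecificationEquation, ratings: ComponentRatings
) -> TaskDifficulty:
    """Predicted task difficulty, unrounded and rounded to 2 decimals."""
    raw = equation.predict(ratings)
    return TaskDifficulty(raw=raw, rounded=round_half_away(raw, 2))


def predict_table(equation: SpecificationEquation, table: TaskTable) -> np.ndarray:
    """Unrounded predicted difficulty for every task, in table order."""
    X = np.asarray(table.ratings_matrix(), dtype=float)
    beta = np.array(
        [equation.coef_body_position, equation.coef_movement, equation.coef_support]
    )
    return equation.intercept + X @ beta


def published_equation() -> SpecificationEquation:
    """The published specification equation defining the GM reference scale.

    TaskDifficulty = 6.76 + 1.23*BodyPosition + 1.21*Movement + 4.93*Support

    The printed two-decimal coefficients are used verbatim: they, not
    higher-precision fitted values, are what the GM-unit reference table
    is built from.
    """
    return SpecificationEquation(
        intercept=6.76,
        coef_body_position=1.23,
        coef_movement=1.21,
        coef_support=4.93,
        provenance="published",
    )
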