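"""Partial credit model simulation and item calibration.

The item difficulty hierarchy that the specification equation is tested
against comes from a Rasch partial credit model (PCM) calibration of a
clinician-scored instrument. That calibration sample is external and not
redistributable, so this module provides the synthetic stand-in: it can

* evaluate PCM category probabilities,
* simulate ordinal response matrices for a person sample,
* recover item difficulties by joint maximum likelihood (JMLE),
* rescale calibrated logits onto any interval target metric (the
  anchoring step downstream makes the choice of metric immaterial up to
  an affine transform), and
* generate noisy "observed difficulty" vectors directly as
  specification-equation predictions plus Gaussian noise, the substrate
  for regression stress-testing.

Model form (Masters' adjacent-category PCM): for an item with
categories 0..m and step difficulties b_1..b_m (b_j = delta + tau_j,
delta the item difficulty, tau_j the centred thresholds),

    P(X = k | theta) ∝ exp( sum_{j<=k} (theta - b_j) ),   empty sum = 0.

Estimation is joint (unconditional) maximum likelihood with alternating
Newton-Raphson updates of person and item parameters, items centred to
mean-zero difficulty. Persons with all-minimum or all-maximum response
patterns and items observed in fewer than two categories have no finite
MLE and are excluded before estimation. Missing responses are treated as
ignorably missing and simply skipped in the likelihood.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .spec_equation import SpecificationEquation, predict_table
from .task_schema import TaskTable

__all__ = [
    "MISSING",
    "PCMItem",
    "PersonSample",
    "ResponseMatrix",
    "CalibrationConfig",
    "CalibrationResult",
    "AbilityEstimate",
    "pcm_category_probabilities",
    "simulate_responses",
    "calibrate_item_difficulties",
    "estimate_person_ability",
    "rescale_logits",
    "generate_difficulty_dataset",
    "write_response_matrix",
    "read_response_matrix",
]

#: Marker for a missing response inside a ResponseMatrix data array.
MISSING: int = -1

# parameters are boxed during Newton iteration; logits beyond this are
# indistinguishable in practice and only invite overflow
_PARAM_BOUND = 10.0
_MAX_NEWTON_STEP = 1.0


@dataclass(frozen=True)
class PCMItem:
    """One partial-credit item: difficulty delta and centred thresholds tau.

    ``thresholds`` has one entry per category step (n_categories - 1
    entries) and sums to zero; the j-th step difficulty is
    ``difficulty + thresholds[j]``.
    """

    difficulty: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) < 1:
            raise ValueError("an item needs at least one category step")
        values = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.isfinite(values)) or not np.isfinite(self.difficulty):
            raise ValueError("item parameters must be finite")
        if abs(values.sum()) > 1e-6:
            raise ValueError(
                "thresholds must sum to zero (centering convention); "
                "use PCMItem.from_steps for uncentred step difficulties"
            )

    @classmethod
    def from_steps(cls, steps: Sequence[float]) -> "PCMItem":
        """Build an item from raw step difficulties b_1..b_m."""
        steps = np.asarray(steps, dtype=float)
        delta = float(steps.mean())
        return cls(difficulty=delta, thresholds=tuple(steps - delta))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def step_difficulties(self) -> np.ndarray:
        return self.difficulty + np.asarray(self.thresholds, dtype=float)


@dataclass(frozen=True)
class PersonSample:
    """A sample of person abilities theta, in logits."""

    abilities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.abilities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("abilities must be a non-empty 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError("abilities must be finite")
        object.__setattr__(self, "abilities", arr)

    @classmethod
    def normal(cls, n: int, mean: float = 0.0, sd: float = 1.0, seed: int = 0) -> "PersonSample":
        """Draw ``n`` abilities from N(mean, sd^2)."""
        if n <= 0:
            raise ValueError("n must be positive")
        if sd < 0:
            raise ValueError("sd must be non-negative")
        rng = np.random.default_rng(seed)
        return cls(rng.normal(mean, sd, size=n))

    def __len__(self) -> int:
        return len(self.abilities)


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items grid of ordinal scores, ``MISSING`` marking gaps."""

    data: np.ndarray
    n_categories: tuple[int, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=int)
        if data.ndim != 2:
            raise ValueError("response data must be 2-D (persons x items)")
        if data.shape[1] != len(self.n_categories):
            raise ValueError("n_categories must list one entry per item column")
        for i, k in enumerate(self.n_categories):
            col = data[:, i]
            observed = col[col != MISSING]
            if observed.size and (observed.min() < 0 or observed.max() >= k):
                raise ValueError(f"item column {i} holds categories outside 0..{k - 1}")
        object.__setattr__(self, "data", data)

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CalibrationConfig:
    """JMLE settings: convergence is declared when the largest absolute
    parameter change in an iteration drops below ``tol``.

    ``bias_correction`` applies Wright's (I-1)/I shrinkage to the final
    centred item estimates. JMLE is inconsistent because person
    parameters are estimated jointly; the spread of item estimates is
    inflated by roughly I/(I-1) (a factor of 2 in the two-item
    dichotomous case), and this standard heuristic removes most of it.
    """

    tol: float = 1e-6
    max_iter: int = 200
    bias_correction: bool = True


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated item parameters on the centred logit metric.

    ``difficulties`` and ``thresholds`` are aligned to the input item
    columns; excluded (inestimable) items carry NaN / None. Included
    difficulties sum to zero (identification constraint).
    """

    difficulties: np.ndarray
    thresholds: tuple[Optional[tuple[float, ...]], ...]
    standard_errors: np.ndarray
    converged: bool
    iterations: int
    excluded_items: tuple[int, ...]

    @property
    def included_items(self) -> tuple[int, ...]:
        return tuple(
            i for i in range(len(self.difficulties)) if i not in self.excluded_items
        )


@dataclass(frozen=True)
class AbilityEstimate:
    """A person ability MLE, or a labelled boundary for extreme patterns.

    For all-minimum (``bound='min'``) or all-maximum (``bound='max'``)
    response patterns no finite MLE exists; ``theta`` is then -inf/+inf
    and ``extreme`` is True — the value is a labelled boundary, not an
    estimate.
    """

    theta: float
    se: float
    extreme: bool
    bound: Optional[str] = None


def pcm_category_probabilities(ability: float, item: PCMItem) -> np.ndarray:
    """Category probabilities P(X = 0..m | theta) under the PCM.

    Probability of category k is proportional to
    exp(sum_{j<=k}(theta - b_j)) with the empty sum equal to 0; the
    returned vector has length ``item.n_categories`` and sums to 1.
    """
    cum = np.concatenate([[0.0], np.cumsum(ability - item.step_difficulties)])
    cum -= cum.max()  # overflow guard; invariant under normalization
    p = np.exp(cum)
    return p / p.sum()


def simulate_responses(
    items: Sequence[PCMItem], persons: PersonSample, seed: int
) -> ResponseMatrix:
    """Draw one ordinal response per (person, item) cell, independently.

    The same (items, persons, seed) triple always yields the same
    matrix.
    """
    items = list(items)
    if not items:
        raise ValueError("need at least one item")
    rng = np.random.default_rng(seed)
    theta = persons.abilities
    n = len(theta)
    data = np.empty((n, len(items)), dtype=int)
    for i, item in enumerate(items):
        steps = item.step_difficulties
        cum = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(theta[:, None] - steps[None, :], axis=1)], axis=1
        )
        cum -= cum.max(axis=1, keepdims=True)
        p = np.exp(cum)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        data[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return ResponseMatrix(data=data, n_categories=tuple(it.n_categories for it in items))


def _category_probs(theta: np.ndarray, cum_b: np.ndarray, k_mask: np.ndarray) -> np.ndarray:
    """P[p, i, k] for all persons/items at once (padded categories masked)."""
    k = np.arange(cum_b.shape[1])
    logits = theta[:, None, None] * k[None, None, :] - cum_b[None, :, :]
    logits = np.where(k_mask[None, :, :], logits, -np.inf)
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=2, keepdims=True)
    return p


def calibrate_item_difficulties(
    responses: ResponseMatrix, config: Optional[CalibrationConfig] = None
) -> CalibrationResult:
    """JMLE calibration of PCM item difficulties from a response matrix.

    Items whose non-missing responses fall in fewer than two distinct
    categories are inestimable: they are excluded with a warning and
    reported in ``excluded_items``. Observed categories with gaps (an
    intermediate category never used) are collapsed onto consecutive
    integers for estimation, the standard pragmatic treatment. Persons
    with extreme (all-minimum / all-maximum) patterns are dropped from
    the likelihood. Standard errors come from the inverse Hessian of
    each item's step parameters at the solution.
    """
    config = config or CalibrationConfig()
    data = np.asarray(responses.data, dtype=int)
    if data.size == 0:
        raise ValueError("empty response matrix")

    n_items_all = data.shape[1]
    excluded: list[int] = []
    cat_maps: dict[int, np.ndarray] = {}
    for i in range(n_items_all):
        col = data[:, i]
        observed = np.unique(col[col != MISSING])
        if observed.size < 2:
            warnings.warn(
                f"item column {i} has responses in fewer than 2 categories; "
                "difficulty inestimable, item excluded",
                stacklevel=2,
            )
            excluded.append(i)
        else:
            cat_maps[i] = observed

    included = [i for i in range(n_items_all) if i not in excluded]
    if not included:
        raise ValueError("no estimable items in the response matrix")

    # collapse observed categories onto 0..k-1 per included item
    X = np.full((data.shape[0], len(included)), MISSING, dtype=int)
    K = np.empty(len(included), dtype=int)
    for j, i in enumerate(included):
        col = data[:, i]
        mask = col != MISSING
        X[mask, j] = np.searchsorted(cat_maps[i], col[mask])
        K[j] = cat_maps[i].size

    # drop persons with no responses or extreme patterns
    obs = X != MISSING
    score = np.where(obs, X, 0).sum(axis=1)
    max_score = (obs * (K - 1)[None, :]).sum(axis=1)
    keep = obs.any(axis=1) & (score > 0) & (score < max_score)
    if not keep.any():
        raise ValueError("no persons with non-extreme response patterns")
    X, obs = X[keep], obs[keep]
    score, max_score = score[keep], max_score[keep]

    n_persons, n_items = X.shape
    k_max = int(K.max())
    step_mask = np.arange(k_max - 1)[None, :] < (K - 1)[:, None]   # valid steps
    cat_mask = np.arange(k_max)[None, :] < K[:, None]              # valid categories

    # initial values: logit of relative score for persons, zero steps
    frac = np.clip(score / max_score, 0.02, 0.98)
    theta = np.log(frac / (1 - frac))
    B = np.zeros((n_items, k_max - 1))  # step difficulties, padded

    ks = np.arange(k_max)
    x_safe = np.where(obs, X, 0)
    # indicator [x >= j] for steps j = 1..k_max-1, zero where missing
    x_ge = (x_safe[:, :, None] >= np.arange(1, k_max)[None, None, :]) & obs[:, :, None]

    converged = False
    iteration = 0
    for iteration in range(1, config.max_iter + 1):
        B_old, theta_old = B.copy(), theta.copy()

        # --- item step update (Newton per item, persons fixed) ---
        cum_b = np.concatenate([np.zeros((n_items, 1)), np.cumsum(B, axis=1)], axis=1)
        P = _category_probs(theta, cum_b, cat_mask)
        P = np.where(obs[:, :, None], P, 0.0)
        # P(X >= j) for j = 1..k_max-1
        p_ge = P[:, :, ::-1].cumsum(axis=2)[:, :, ::-1][:, :, 1:]
        grad = (x_ge - p_ge).sum(axis=0)  # dloglik/db_j, n_items x (k_max-1)
        for j in range(n_items):
            m = K[j] - 1
            pg = p_ge[obs[:, j], j, :m]
            # H[a, b] = sum_p P(X>=max(a,b)) - P(X>=a) P(X>=b); m is tiny
            H = np.empty((m, m))
            for a in range(m):
                for b in range(m):
                    H[a, b] = pg[:, max(a, b)].sum() - (pg[:, a] * pg[:, b]).sum()
            try:
                delta = np.linalg.solve(H, grad[j, :m])
            except np.linalg.LinAlgError:
                delta = grad[j, :m] / max(np.diag(H).max(), 1e-8)
            delta = np.clip(delta, -_MAX_NEWTON_STEP, _MAX_NEWTON_STEP)
            B[j, :m] -= delta
        B = np.clip(B, -_PARAM_BOUND, _PARAM_BOUND) * step_mask

        # --- recenter: mean item difficulty = 0 ---
        deltas = B.sum(axis=1) / (K - 1)
        shift = deltas.mean()
        B = (B - shift) * step_mask
        theta = theta - shift

        # --- person update (Newton per person, items fixed) ---
        cum_b = np.concatenate([np.zeros((n_items, 1)), np.cumsum(B, axis=1)], axis=1)
        P = _category_probs(theta, cum_b, cat_mask)
        Pobs = np.where(obs[:, :, None], P, 0.0)
        ek = (Pobs * ks[None, None, :]).sum(axis=2)
        vk = (Pobs * ks[None, None, :] ** 2).sum(axis=2) - ek**2
        g = (np.where(obs, x_safe - ek, 0.0)).sum(axis=1)
        info = np.maximum(vk.sum(axis=1), 1e-8)
        theta = theta + np.clip(g / info, -_MAX_NEWTON_STEP, _MAX_NEWTON_STEP)
        theta = np.clip(theta, -_PARAM_BOUND, _PARAM_BOUND)

        change = max(np.abs(B - B_old).max(), np.abs(theta - theta_old).max())
        if change < config.tol:
            converged = True
            break

    # item standard errors from the step-parameter Hessian at the solution
    cum_b = np.concatenate([np.zeros((n_items, 1)), np.cumsum(B, axis=1)], axis=1)
    P = _category_probs(theta, cum_b, cat_mask)
    P = np.where(obs[:, :, None], P, 0.0)
    p_ge = P[:, :, ::-1].cumsum(axis=2)[:, :, ::-1][:, :, 1:]
    ses = np.empty(n_items)
    for j in range(n_items):
        m = K[j] - 1
        pg = p_ge[obs[:, j], j, :m]
        H = np.empty((m, m))
        for a in range(m):
            for b in range(m):
                H[a, b] = pg[:, max(a, b)].sum() - (pg[:, a] * pg[:, b]).sum()
        try:
            cov = np.linalg.inv(H)
            ses[j] = float(np.sqrt(max(cov.sum() / m**2, 0.0)))
        except np.linalg.LinAlgError:
            ses[j] = float("nan")

    deltas = B.sum(axis=1) / (K - 1)
    deltas = deltas - deltas.mean()  # exact identification constraint
    correction = (n_items - 1) / n_items if config.bias_correction and n_items > 1 else 1.0
    deltas = deltas * correction

    difficulties = np.full(n_items_all, np.nan)
    std_errors = np.full(n_items_all, np.nan)
    thresholds: list[Optional[tuple[float, ...]]] = [None] * n_items_all
    for j, i in enumerate(included):
        difficulties[i] = deltas[j]
        std_errors[i] = ses[j]
        m = K[j] - 1
        tau = (B[j, :m] - B[j, :m].mean()) * correction
        thresholds[i] = tuple(tau)

    return CalibrationResult(
        difficulties=difficulties,
        thresholds=tuple(thresholds),
        standard_errors=std_errors,
        converged=converged,
        iterations=iteration,
        excluded_items=tuple(excluded),
    )


def estimate_person_ability(
    responses_row: Sequence[int], items: Sequence[PCMItem], tol: float = 1e-8
) -> AbilityEstimate:
    """ML ability estimate for one person, item parameters fixed.

    All-minimum and all-maximum patterns have no finite MLE and come
    back as labelled boundary results (theta = -inf/+inf,
    ``extreme=True``) rather than numbers posing as estimates.
    """
    row = np.asarray(responses_row, dtype=int)
    items = list(items)
    if row.shape != (len(items),):
        raise ValueError("response row length must match the item list")
    obs_idx = [i for i in range(len(items)) if row[i] != MISSING]
    if not obs_idx:
        raise ValueError("no non-missing responses")
    score = sum(int(row[i]) for i in obs_idx)
    max_score = sum(items[i].n_categories - 1 for i in obs_idx)
    if score == 0:
        return AbilityEstimate(float("-inf"), float("nan"), extreme=True, bound="min")
    if score == max_score:
        return AbilityEstimate(float("inf"), float("nan"), extreme=True, bound="max")

    theta = 0.0
    info = 1.0
    for _ in range(200):
        g = 0.0
        info = 0.0
        for i in obs_idx:
            p = pcm_category_probabilities(theta, items[i])
            k = np.arange(len(p))
            ek = float((k * p).sum())
            g += row[i] - ek
            info += float((k**2 * p).sum()) - ek**2
        step = np.clip(g / max(info, 1e-10), -_MAX_NEWTON_STEP, _MAX_NEWTON_STEP)
        theta += step
        if abs(step) < tol:
            break
    return AbilityEstimate(float(theta), float(1.0 / np.sqrt(max(info, 1e-10))), extreme=False)


def rescale_logits(
    difficulties: Sequence[float], low_target: float, high_target: float
) -> np.ndarray:
    """Affine map of a logit vector sending its min/max to the targets.

    Order is preserved (the map is increasing); constant input has no
    such map and raises.
    """
    d = np.asarray(difficulties, dtype=float)
    if not low_target < high_target:
        raise ValueError("low_target must be below high_target")
    lo, hi = np.nanmin(d), np.nanmax(d)
    if not lo < hi:
        raise ValueError("cannot rescale a constant difficulty vector")
    return low_target + (d - lo) * (high_target - low_target) / (hi - lo)


def generate_difficulty_dataset(
    equation: SpecificationEquation,
    table: TaskTable,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Synthetic observed difficulties: equation predictions + N(0, sd^2).

    One value per task, in table order; ``noise_sd = 0`` reproduces the
    predictions exactly, and the same seed always yields the same
    vector. The default residual scale used throughout the package's
    study conditions is 6.09 difficulty units, the residual RMSE of the
    reference three-component fit.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    preds = predict_table(equation, table)
    if noise_sd == 0:
        return preds
    rng = np.random.default_rng(seed)
    return preds + rng.normal(0.0, noise_sd, size=len(preds))


def write_response_matrix(matrix: ResponseMatrix, dest: Union[str, Path, TextIO]) -> None:
    """Write a response matrix as CSV: persons as rows, items as columns,
    blank cell = missing."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as handle:
            write_response_matrix(matrix, handle)
        return
    writer = csv.writer(dest)
    writer.writerow([f"item_{i + 1}" for i in range(matrix.n_items)])
    for row in matrix.data:
        writer.writerow(["" if v == MISSING else int(v) for v in row])


def read_response_matrix(
    source: Union[str, Path, TextIO], n_categories: Optional[Sequence[int]] = None
) -> ResponseMatrix:
    """Read a response-matrix CSV (blank cell = missing).

    If ``n_categories`` is not given it is inferred per item as one more
    than the largest observed category.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            return read_response_matrix(handle, n_categories)
    reader = csv.reader(source)
    header = next(reader, None)
    if header is None:
        raise ValueError("empty response-matrix file")
    rows = [
        [MISSING if cell.strip() == "" else int(cell) for cell in row]
        for row in reader
        if row
    ]
    if not rows:
        raise ValueError("response-matrix file has no data rows")
    data = np.asarray(rows, dtype=int)
    if n_categories is None:
        n_categories = [max(int(data[:, i].max()) + 1, 2) for i in range(data.shape[1])]
    return ResponseMatrix(data=data, n_categories=tuple(n_categories))
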