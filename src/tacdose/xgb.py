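"""Gradient-boosted trough models.

The mechanism-informed variant cannot learn (alpha, ke) by gradient
descent the way the recurrent model does, so the elimination rate is
fixed externally (population value 0.0578 1/h by default, or a
per-patient estimate from the Bayesian forecaster) and the booster is
trained to predict the composite parameter alpha from lag features built
on the two most recent trough measurements.  The predicted alpha is then
multiplied by the remaining drug amount at the target time to produce
the trough — so predictions inherit exact dose linearity at frozen
alpha.  Rows are weighted by the squared remaining amount, which makes
the alpha-scale squared error identical to the trough-scale squared
error the protocol minimizes.

The purely data-driven ablation drops the remaining-amount and
empirical-alpha lags, adds the daily dose, and predicts the trough
directly.

Hyperparameters are tuned by nested cross-validation: within each outer
training set an inner four-fold (patient-grouped) grid search selects
the setting with the lowest mean trough MSE, which is then refit on the
full outer training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from xgboost import XGBRegressor

from .data import LagFeatureRow, lag_matrix
from .gru import PredictionResult
from .pk_core import PKParams

__all__ = [
    "XgbConfig",
    "MechanismXgb",
    "DataDrivenXgb",
    "train_xgb",
    "train_xgb_nested_cv",
    "DEFAULT_KE",
]

#: Fixed population elimination rate constant (1/h) used when no
#: individual estimate is supplied.
DEFAULT_KE = 0.0578

_ALPHA_FLOOR = 1e-6

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 4],
    "learning_rate": [0.1],
    "n_estimators": [100, 300],
    "subsample": [1.0],
}


@dataclass(frozen=True)
class XgbConfig:
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    ke_mode: str = "fixed_population"  # or "per_patient"
    fixed_ke: float = DEFAULT_KE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fixed_ke < 1):
            raise ValueError(f"fixed_ke must be in (0, 1) 1/h, got {self.fixed_ke}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        if self.ke_mode not in ("fixed_population", "per_patient"):
            raise ValueError(f"unknown ke_mode {self.ke_mode!r}")


def _make_regressor(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        objective="reg:squarederror",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        **params,
    )


class MechanismXgb:
    """Boosted alpha-regressor + trough equation."""

    model_name = "xgb_mech"

    def __init__(self, cfg: XgbConfig, params: dict):
        self.cfg = cfg
        self.params = params
        self.reg = _make_regressor(params, cfg.seed)
        self.feature_names: tuple[str, ...] = ()

    def fit(self, rows: Sequence[LagFeatureRow]) -> "MechanismXgb":
        X, names = lag_matrix(rows, mechanism=True)
        self.feature_names = names
        rem = np.array([r.remaining_at_target for r in rows])
        if np.any(rem <= 0):
            raise ValueError("non-positive remaining drug amount in training rows")
        y_alpha = np.array([r.target_conc for r in rows]) / rem
        # weight by remaining^2 so alpha-MSE == trough-MSE
        self.reg.fit(X, y_alpha, sample_weight=rem**2)
        return self

    def predict_alpha(self, rows: Sequence[LagFeatureRow]) -> np.ndarray:
        X, _ = lag_matrix(rows, mechanism=True)
        return np.maximum(self.reg.predict(X).astype(float), _ALPHA_FLOOR)

    def predict_batch(self, rows: Sequence[LagFeatureRow], ke: float | None = None) -> list[PredictionResult]:
        ke = self.cfg.fixed_ke if ke is None else ke
        alphas = self.predict_alpha(rows)
        out = []
        for row, a in zip(rows, alphas):
            if row.remaining_at_target <= 0:
                raise ValueError(
                    f"patient {row.patient_id}: non-positive remaining drug "
                    "amount at target time"
                )
            pred = float(a) * row.remaining_at_target
            out.append(
                PredictionResult(
                    row.patient_id, row.target_index, pred, row.target_conc,
                    params=PKParams(float(a), ke), model_name=self.model_name,
                )
            )
        return out

    def predict_trough(self, row: LagFeatureRow) -> PredictionResult:
        return self.predict_batch([row])[0]


class DataDrivenXgb:
    """Direct trough prediction from the ablated feature set."""

    model_name = "xgb_dd"

    def __init__(self, cfg: XgbConfig, params: dict):
        self.cfg = cfg
        self.params = params
        self.reg = _make_regressor(params, cfg.seed)
        self.feature_names: tuple[str, ...] = ()

    def fit(self, rows: Sequence[LagFeatureRow]) -> "DataDrivenXgb":
        X, names = lag_matrix(rows, mechanism=False)
        self.feature_names = names
        y = np.array([r.target_conc for r in rows])
        self.reg.fit(X, y)
        return self

    def predict_batch(self, rows: Sequence[LagFeatureRow]) -> list[PredictionResult]:
        X, _ = lag_matrix(rows, mechanism=False)
        pred = np.maximum(self.reg.predict(X).astype(float), 0.0)
        return [
            PredictionResult(
                row.patient_id, row.target_index, float(p), row.target_conc,
                params=None, model_name=self.model_name,
            )
            for row, p in zip(rows, pred)
        ]

    def predict_trough(self, row: LagFeatureRow) -> PredictionResult:
        return self.predict_batch([row])[0]


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _trough_mse(model, rows: Sequence[LagFeatureRow]) -> float:
    preds = model.predict_batch(rows)
    return float(np.mean([(p.predicted - p.observed) ** 2 for p in preds]))


def _patient_folds(rows: Sequence[LagFeatureRow], k: int, seed: int) -> list[np.ndarray]:
    """Row-index folds grouped by patient."""
    pids = sorted({r.patient_id for r in rows})
    rng = np.random.default_rng(seed)
    rng.shuffle(pids)
    assignment = {pid: i % k for i, pid in enumerate(pids)}
    return [
        np.array([j for j, r in enumerate(rows) if assignment[r.patient_id] == f])
        for f in range(k)
    ]


def train_xgb(
    rows: Sequence[LagFeatureRow], cfg: XgbConfig, *, mechanism: bool = True
) -> MechanismXgb | DataDrivenXgb:
    """Fit a single booster with inner 4-fold grid search on ``rows``."""
    best, _ = _inner_select(rows, cfg, mechanism)
    cls = MechanismXgb if mechanism else DataDrivenXgb
    return cls(cfg, best).fit(rows)


def _inner_select(
    rows: Sequence[LagFeatureRow], cfg: XgbConfig, mechanism: bool
) -> tuple[dict, dict[str, float]]:
    """Inner four-fold patient-grouped grid search; returns the winning
    hyperparameters and the mean inner trough-MSE per grid point."""
    cls = MechanismXgb if mechanism else DataDrivenXgb
    points = _grid_points(cfg.grid)
    if len(points) == 1:
        return points[0], {repr(points[0]): float("nan")}
    n_inner = min(4, len({r.patient_id for r in rows}))
    folds = _patient_folds(rows, n_inner, cfg.seed)
    scores: dict[str, float] = {}
    best_params, best_score = None, np.inf
    for params in points:
        mses = []
        for f in range(n_inner):
            test_idx = set(folds[f].tolist())
            train_rows = [r for j, r in enumerate(rows) if j not in test_idx]
            test_rows = [rows[j] for j in sorted(test_idx)]
            if not train_rows or not test_rows:
                continue
            model = cls(cfg, params).fit(train_rows)
            mses.append(_trough_mse(model, test_rows))
        score = float(np.mean(mses))
        scores[repr(params)] = score
        if score < best_score:
            best_params, best_score = params, score
    return best_params, scores


def train_xgb_nested_cv(
    rows: Sequence[LagFeatureRow],
    cfg: XgbConfig,
    outer_folds: Sequence[set[str]],
    *,
    mechanism: bool = True,
) -> list[dict]:
    """Nested cross-validation over patient-level outer folds.

    ``outer_folds`` is a sequence of disjoint patient-id sets.  For each
    outer fold an inner four-fold grid search runs on the outer-training
    rows, the winner is refit on the full outer-training set and
    evaluated once on the outer-test rows.  Returns one record per fold:
    ``{"model", "best_params", "predictions", "test_mse"}``.
    """
    seen: set[str] = set()
    for fold in outer_folds:
        overlap = seen & fold
        if overlap:
            raise ValueError(f"patient(s) {sorted(overlap)} appear in multiple outer folds")
        seen |= fold
    cls = MechanismXgb if mechanism else DataDrivenXgb
    results = []
    for f, test_pids in enumerate(outer_folds):
        train_rows = [r for r in rows if r.patient_id not in test_pids]
        test_rows = [r for r in rows if r.patient_id in test_pids]
        best, _ = _inner_select(train_rows, cfg, mechanism)
        model = cls(cfg, best).fit(train_rows)
        preds = model.predict_batch(test_rows) if test_rows else []
        results.append(
            {
                "fold": f,
                "model": model,
                "best_params": best,
                "predictions": preds,
                "test_mse": float(
                    np.mean([(p.predicted - p.observed) ** 2 for p in preds])
                ) if preds else float("nan"),
            }
        )
    return results
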