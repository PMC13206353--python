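"""Cross-validation protocol, the six-metric suite, target-attainment
stratification and feature-importance procedures.

Metric definitions (predictions yhat, observations y > 0):

    MSE    = mean((yhat - y)^2)                       [ng^2/mL^2]
    MAE    = mean(|yhat - y|)                         [ng/mL]
    R^2    = 1 - SSE/SST
    MPE    = 100 * mean((yhat - y) / y)               [%; + = overprediction]
    RMSRPE = 100 * sqrt(mean(((yhat - y) / y)^2))     [%]
    P_k    = 100 * fraction with |yhat - y| / y <= k/100

Folds are assigned at the patient level (all of a patient's samples land
in one fold) and stratified on per-patient trough-count bins {2, 3, >=4}
so fold difficulty is balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import PatientRecord
from .gru import PredictionResult

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "make_folds",
    "crossvalidate",
    "target_attainment",
    "permutation_importance",
    "gain_importance",
]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    mae: float
    r2: float | None
    mpe: float
    rmsrpe: float
    p10: float
    p20: float
    p30: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mse": self.mse, "mae": self.mae, "r2": self.r2, "mpe": self.mpe,
            "rmsrpe": self.rmsrpe, "p10": self.p10, "p20": self.p20,
            "p30": self.p30, "n": self.n,
        }


def compute_metrics(pairs: Sequence[tuple[float, float]]) -> MetricsReport:
    """Six-metric suite over (predicted, observed) pairs.

    Observations must be strictly positive (relative metrics).  With a
    single pair R^2 is undefined and reported as ``None``.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (predicted, observed) pair")
    yhat = np.array([p for p, _ in pairs], dtype=float)
    y = np.array([o for _, o in pairs], dtype=float)
    if np.any(y <= 0):
        raise ValueError("observed concentrations must be > 0 for relative metrics")
    err = yhat - y
    rel = err / y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = None if len(pairs) < 2 or sst == 0 else 1.0 - float(np.sum(err**2)) / sst
    return MetricsReport(
        mse=float(np.mean(err**2)),
        mae=float(np.mean(np.abs(err))),
        r2=r2,
        mpe=100.0 * float(np.mean(rel)),
        rmsrpe=100.0 * float(np.sqrt(np.mean(rel**2))),
        p10=100.0 * float(np.mean(np.abs(rel) <= 0.10)),
        p20=100.0 * float(np.mean(np.abs(rel) <= 0.20)),
        p30=100.0 * float(np.mean(np.abs(rel) <= 0.30)),
        n=len(pairs),
    )


def _strat_bin(p: PatientRecord) -> int:
    n = len(p.troughs)
    return 2 if n <= 2 else (3 if n == 3 else 4)


def make_folds(
    patients: Sequence[PatientRecord], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Patient-level stratified fold assignment.

    Patients are grouped by trough-count bin {2, 3, >=4}; within each bin
    the order is shuffled (seeded) and folds are dealt round-robin, so
    every patient lands in exactly one fold and bins are balanced within
    one patient across folds.  Deterministic given ``seed``.
    """
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for b in sorted({_strat_bin(p) for p in patients}):
        pids = sorted(p.patient_id for p in patients if _strat_bin(p) == b)
        order = rng.permutation(len(pids))
        for i, j in enumerate(order):
            assignment[pids[j]] = (offset + i) % k
        offset += len(pids)
    return assignment


FitPredict = Callable[
    [Sequence[PatientRecord], Sequence[PatientRecord]], list[PredictionResult]
]


def crossvalidate(
    fit_predict: FitPredict,
    patients: Sequence[PatientRecord],
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Patient-level k-fold cross-validation of any model pipeline.

    ``fit_predict(train_patients, test_patients)`` must train from
    scratch on the training patients and return one prediction per
    held-out target trough.  Both the fold-averaged and the
    pooled-prediction metric reports are returned (pooled is the
    deterministic aggregation used elsewhere in the package).
    """
    assignment = make_folds(patients, k=k, seed=seed)
    per_fold: list[MetricsReport] = []
    pooled: list[PredictionResult] = []
    for f in range(k):
        train = [p for p in patients if assignment[p.patient_id] != f]
        test = [p for p in patients if assignment[p.patient_id] == f]
        if not test:
            continue
        preds = fit_predict(train, test)
        test_ids = {p.patient_id for p in test}
        leaked = [pr.patient_id for pr in preds if pr.patient_id not in test_ids]
        if leaked:
            raise RuntimeError(f"fold {f}: predictions for non-test patients {leaked[:3]}")
        pooled.extend(preds)
        per_fold.append(compute_metrics([(p.predicted, p.observed) for p in preds]))
    return {
        "fold_assignment": assignment,
        "per_fold": per_fold,
        "fold_mean_mse": float(np.mean([m.mse for m in per_fold])),
        "pooled": compute_metrics([(p.predicted, p.observed) for p in pooled]),
        "predictions": pooled,
    }


def predictions_frame(preds: Sequence[PredictionResult],
                      assignment: dict[str, int] | None = None) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.patient_id,
            "target_index": p.target_index,
            "observed": p.observed,
            "predicted": p.predicted,
            "model_name": p.model_name,
            "fold": assignment.get(p.patient_id, -1) if assignment else -1,
        }
        for p in preds
    ]
    return pd.DataFrame(rows)


def target_attainment(
    table: pd.DataFrame, target: tuple[float, float] = (8.0, 12.0)
) -> dict:
    """Stratified target-attainment summary.

    ``table`` needs columns ``observed`` (the subsequent trough, ng/mL),
    ``category`` in {"within", "below", "above", "no_recommendation"}
    (administered dose vs the model-recommended range) and
    ``measurement_index`` (chronological trough number, >= 2).  For each
    stratum the percentage of troughs below / within / above the closed
    target window is reported, plus the within-target trend by
    measurement index.
    """
    lo, hi = target

    def bin_pcts(obs: np.ndarray) -> dict:
        n = obs.size
        if n == 0:
            return {"n": 0, "below_pct": None, "within_pct": None, "above_pct": None}
        below = float(np.mean(obs < lo)) * 100.0
        within = float(np.mean((obs >= lo) & (obs <= hi))) * 100.0
        above = float(np.mean(obs > hi)) * 100.0
        return {"n": int(n), "below_pct": below, "within_pct": within, "above_pct": above}

    out: dict = {"all": bin_pcts(table["observed"].to_numpy(float))}
    for cat in ("within", "below", "above", "no_recommendation"):
        sub = table[table["category"] == cat]
        out[cat] = bin_pcts(sub["observed"].to_numpy(float))
    trend = {}
    for idx, grp in table.groupby("measurement_index"):
        trend[int(idx)] = {
            "all": bin_pcts(grp["observed"].to_numpy(float)),
            "within": bin_pcts(
                grp.loc[grp["category"] == "within", "observed"].to_numpy(float)
            ),
        }
    out["by_measurement_index"] = trend
    return out


def permutation_importance(
    predict_mse: Callable[[np.ndarray], float],
    X_columns: np.ndarray,
    feature_names: Sequence[str],
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Generic permutation importance: Delta-MSE per feature.

    ``X_columns`` is any array whose last axis indexes features (rows for
    tabular models, pooled real time-steps for sequence models);
    ``predict_mse`` maps a (possibly permuted) copy to a test MSE.  Each
    feature column is shuffled across the test set ``n_repeats`` times
    and the mean increase over the baseline MSE is reported; a constant
    (or unused) feature scores zero up to permutation noise.
    """
    rng = np.random.default_rng(seed)
    base = predict_mse(X_columns)
    out: dict[str, float] = {}
    for j, name in enumerate(feature_names):
        deltas = []
        col = X_columns[..., j].reshape(-1)
        if np.all(col == col[0]):
            out[name] = 0.0
            continue
        for _ in range(n_repeats):
            Xp = X_columns.copy()
            flat = Xp[..., j].reshape(-1)
            perm = rng.permutation(flat.size)
            Xp[..., j] = flat[perm].reshape(Xp[..., j].shape)
            deltas.append(predict_mse(Xp) - base)
        out[name] = float(np.mean(deltas))
    return out


def gain_importance(model) -> dict[str, float]:
    """Gain-based feature-importance shares (%) of a fitted booster;
    non-negative and summing to 100."""
    booster = model.reg.get_booster()
    raw = booster.get_score(importance_type="gain")
    names = model.feature_names
    gains = np.zeros(len(names))
    for key, g in raw.items():
        idx = int(key[1:]) if key.startswith("f") else names.index(key)
        gains[idx] = g
    total = gains.sum()
    if total <= 0:
        return {n: 0.0 for n in names}
    return {n: float(100.0 * g / total) for n, g in zip(names, gains)}
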