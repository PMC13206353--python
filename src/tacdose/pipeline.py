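"""End-to-end model pipelines over validated patient records.

Provides the ``fit_predict`` closures consumed by
:func:`tacdose.evaluation.crossvalidate` for each of the five model
variants (mechanism-informed GRU / XGBoost, their purely data-driven
ablations, and the sequential MAP forecaster), plus simple versioned
checkpoint persistence.
"""

from __future__ import annotations

import pickle
from pathlib import Path
from typing import Sequence

from .bayes import PopPrior, map_update, sequential_forecasts
from .data import PatientRecord, build_lag_features, build_sequences
from .gru import GruConfig, PredictionResult, train_datadriven_gru, train_gru
from .xgb import XgbConfig, train_xgb

MODEL_NAMES = ("gru_mech", "gru_dd", "xgb_mech", "xgb_dd", "bayes")

CHECKPOINT_SCHEMA_VERSION = 1


def _sequences(patients: Sequence[PatientRecord]):
    out = []
    for p in patients:
        out.extend(build_sequences(p))
    return out


def _lag_rows(patients: Sequence[PatientRecord], cfg: XgbConfig, prior: PopPrior):
    rows = []
    for p in patients:
        if cfg.ke_mode == "fixed_population":
            rows.extend(build_lag_features(p, cfg.fixed_ke))
        else:
            # per-patient effective ke from the MAP forecaster, updated
            # sequentially so row k only sees troughs 1..k-1
            for k in range(1, len(p.troughs)):
                est = map_update(prior, p.doses, p.troughs[:k])
                ke = est.cl / est.v
                row = build_lag_features(p, ke)[k - 1]
                rows.append(row)
    return rows


def make_fit_predict(
    model_name: str,
    gru_cfg: GruConfig | None = None,
    xgb_cfg: XgbConfig | None = None,
    prior: PopPrior | None = None,
):
    """Build a ``fit_predict(train_patients, test_patients)`` closure for
    one of: gru_mech, gru_dd, xgb_mech, xgb_dd, bayes."""
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
    gru_cfg = gru_cfg or GruConfig()
    xgb_cfg = xgb_cfg or XgbConfig()
    prior = prior or PopPrior()

    def fit_predict(train, test) -> list[PredictionResult]:
        if model_name == "gru_mech":
            model, _ = train_gru(_sequences(train), gru_cfg)
            return model.predict_batch(_sequences(test))
        if model_name == "gru_dd":
            model, _ = train_datadriven_gru(_sequences(train), gru_cfg)
            return model.predict_batch(_sequences(test))
        if model_name in ("xgb_mech", "xgb_dd"):
            mechanism = model_name == "xgb_mech"
            model = train_xgb(
                _lag_rows(train, xgb_cfg, prior), xgb_cfg, mechanism=mechanism
            )
            return model.predict_batch(_lag_rows(test, xgb_cfg, prior))
        # sequential MAP forecasting needs no training beyond the prior
        preds = []
        for p in test:
            for n, forecast, _est in sequential_forecasts(prior, p.doses, p.troughs):
                preds.append(
                    PredictionResult(
                        p.patient_id, n, forecast, p.troughs[n].concentration,
                        params=None, model_name="bayes",
                    )
                )
        return preds

    return fit_predict


def save_model(model, path: str | Path) -> None:
    """Persist a trained model with its config; versioned."""
    payload = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "class": type(model).__name__,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("schema_version")
    if version != CHECKPOINT_SCHEMA_VERSION:
        raise ValueError(
            f"checkpoint schema version {version} does not match "
            f"{CHECKPOINT_SCHEMA_VERSION}; refusing to load"
        )
    return payload["model"]
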