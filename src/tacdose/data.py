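"""Patient tables, lab imputation, covariate encoding and feature building.

Input layout (all times are decimal hours since the first tacrolimus dose):

* ``doses.csv``   — patient_id, time_h, dose_mg
* ``troughs.csv`` — patient_id, time_h, conc_ng_ml
* ``labs.csv``    — patient_id, analyte, time_h, value
* ``static.csv``  — one row per patient with the static covariate columns

Two feature representations are produced from a validated
:class:`PatientRecord`:

* :func:`build_sequences` — per-trough prediction windows for the
  recurrent model: sample ``k`` uses troughs ``1..k`` as history and
  trough ``k+1`` as target, with dose events up to the target time
  attached so the trough equation can be evaluated downstream;
* :func:`build_lag_features` — one tabular row per target trough for the
  boosted model, holding lag-1/lag-2 blocks (remaining drug amount,
  observed trough, empirical alpha, time-varying labs), time features and
  the static encoding.

No sample ever uses information at or after its own target time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pk_core import DoseEvent, TroughObservation, empirical_alpha, remaining_drug_amount

logger = logging.getLogger(__name__)

__all__ = [
    "LAB_ANALYTES",
    "RACE_LEVELS",
    "STATIC_FEATURE_NAMES",
    "SEQUENCE_STEP_FEATURES",
    "LabSeries",
    "StaticCovariates",
    "PatientRecord",
    "SequenceSample",
    "LagFeatureRow",
    "read_cohort",
    "impute_labs",
    "encode_static",
    "build_sequences",
    "pad_batch",
    "build_lag_features",
    "lag_matrix",
    "LAG_FEATURE_NAMES",
    "DD_LAG_FEATURE_NAMES",
]

LAB_ANALYTES = ("hematocrit", "albumin", "alt", "ast", "creatinine")
RACE_LEVELS = ("Caucasian", "African American", "Other")

#: Default assumed delay between transplantation and the first tacrolimus
#: dose (therapy is initiated within 24 h post-transplant).
DEFAULT_TRANSPLANT_OFFSET_H = 12.0

DEFAULT_WINDOW_HOURS = 168.0
DEFAULT_LLOQ = 1.0


@dataclass
class LabSeries:
    """Time series of one laboratory analyte for one patient."""

    analyte: str
    times: np.ndarray
    values: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size == 0:
            raise ValueError(f"empty lab series for {self.analyte}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite value in lab series {self.analyte}")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.values = self.values[order]
        if self.imputed is None:
            self.imputed = np.zeros(self.times.size, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)[order]


@dataclass(frozen=True)
class StaticCovariates:
    age: float
    sex: str  # {"M", "F"}
    race: str  # RACE_LEVELS
    height_cm: float
    weight_kg: float
    bmi: float
    bsa: float
    smoking: int
    alcohol: int
    cyp3a_inhibitor: int
    cyp3a_inducer: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.race not in RACE_LEVELS:
            raise ValueError(f"unknown race level {self.race!r}; expected {RACE_LEVELS}")
        for name in ("age", "height_cm", "weight_kg", "bmi", "bsa"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("smoking", "alcohol", "cyp3a_inhibitor", "cyp3a_inducer"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0/1")


@dataclass
class PatientRecord:
    """Validated per-patient record: dose, trough and lab series plus
    static covariates.  Invariants: at least two troughs, strictly
    increasing dose times, every trough preceded by at least one dose,
    all event times inside the observation window."""

    patient_id: str
    doses: list[DoseEvent]
    troughs: list[TroughObservation]
    labs: dict[str, LabSeries]
    static: StaticCovariates

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.time)
        self.troughs = sorted(self.troughs, key=lambda o: o.time)
        times = [d.time for d in self.doses]
        if len(times) != len(set(times)):
            raise ValueError(f"patient {self.patient_id}: duplicated dose times")
        if len(self.troughs) < 2:
            raise ValueError(
                f"patient {self.patient_id}: needs >= 2 trough measurements"
            )
        first_dose = self.doses[0].time if self.doses else np.inf
        for obs in self.troughs:
            if obs.time <= first_dose:
                raise ValueError(
                    f"patient {self.patient_id}: trough at {obs.time:g} h is not "
                    f"preceded by any dose (first dose at {first_dose:g} h)"
                )

    def doses_until(self, t: float) -> list[DoseEvent]:
        """Dose events administered strictly before time ``t``."""
        return [d for d in self.doses if d.time < t]

    def lab_at(self, analyte: str, t: float, cutoff: float | None = None) -> float:
        """Imputed lab value at ``t``.  When ``cutoff`` is given only lab
        points observed strictly before it are used (so features built
        for a prediction target never see post-target measurements)."""
        series = self.labs.get(analyte)
        if series is None:
            raise KeyError(f"patient {self.patient_id}: no lab series {analyte!r}")
        if cutoff is not None:
            keep = series.times < cutoff
            if not keep.any():
                keep = np.zeros_like(keep)
                keep[0] = True  # fall back to the earliest measurement
            series = LabSeries(
                series.analyte, series.times[keep], series.values[keep],
                series.imputed[keep],
            )
        return float(impute_labs(series, [t])[0])


@dataclass
class SequenceSample:
    """One recurrent-model prediction window.

    ``features`` has shape (n_steps, n_features); step ``j`` describes
    history trough ``j`` (concentration, inter-dose timing, labs) plus
    the static encoding.  ``doses`` holds every dose event up to (strictly
    before) the target time so that the trough equation can be evaluated
    for the emitted parameters.
    """

    patient_id: str
    target_index: int
    features: np.ndarray
    target_time: float
    target_conc: float
    doses: list[DoseEvent]

    @property
    def n_steps(self) -> int:
        return self.features.shape[0]


@dataclass
class LagFeatureRow:
    """One boosted-model row: named feature values plus the bookkeeping
    needed to turn a predicted alpha back into a trough."""

    patient_id: str
    target_index: int
    values: dict[str, float]
    target_time: float
    target_conc: float
    remaining_at_target: float
    daily_dose: float
    doses: list[DoseEvent]


# --------------------------------------------------------------------------
# reading & validation


_STATIC_COLUMNS = {
    "patient_id",
    "age",
    "sex",
    "race",
    "height_cm",
    "weight_kg",
    "bmi",
    "bsa",
    "smoking",
    "alcohol",
    "cyp3a_inhibitor",
    "cyp3a_inducer",
}


def _require_columns(df: pd.DataFrame, needed: Iterable[str], path: str) -> None:
    missing = set(needed) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")


def read_cohort(
    dose_csv,
    trough_csv,
    labs_csv,
    static_csv,
    *,
    window_hours: float = DEFAULT_WINDOW_HOURS,
    lloq: float = DEFAULT_LLOQ,
) -> list[PatientRecord]:
    """Read and validate the four cohort CSVs.

    Patients failing inclusion rules (fewer than two usable troughs after
    LLOQ censoring, or events outside the window) are dropped with a
    logged reason; structural violations (schema, duplicated dose rows,
    troughs before the first dose) raise ``ValueError``.
    """
    doses = pd.read_csv(dose_csv)
    troughs = pd.read_csv(trough_csv)
    labs = pd.read_csv(labs_csv)
    static = pd.read_csv(static_csv)

    _require_columns(doses, ["patient_id", "time_h", "dose_mg"], str(dose_csv))
    _require_columns(troughs, ["patient_id", "time_h", "conc_ng_ml"], str(trough_csv))
    _require_columns(labs, ["patient_id", "analyte", "time_h", "value"], str(labs_csv))
    _require_columns(static, _STATIC_COLUMNS, str(static_csv))

    if doses.duplicated(subset=["patient_id", "time_h"]).any():
        dup = doses[doses.duplicated(subset=["patient_id", "time_h"], keep=False)]
        raise ValueError(
            f"{dose_csv}: duplicated (patient_id, time_h) dose rows: "
            f"{dup['patient_id'].unique()[:5].tolist()}"
        )
    static = static.set_index("patient_id")
    if static.index.duplicated().any():
        raise ValueError(f"{static_csv}: duplicated patient_id rows")

    records: list[PatientRecord] = []
    for pid, dose_rows in doses.groupby("patient_id", sort=True):
        pid = str(pid)
        if pid not in static.index.astype(str):
            logger.warning("excluding patient %s: no static covariate row", pid)
            continue
        srow = static.loc[static.index.astype(str) == pid].iloc[0]
        try:
            cov = StaticCovariates(
                age=float(srow["age"]),
                sex=str(srow["sex"]),
                race=str(srow["race"]),
                height_cm=float(srow["height_cm"]),
                weight_kg=float(srow["weight_kg"]),
                bmi=float(srow["bmi"]),
                bsa=float(srow["bsa"]),
                smoking=int(srow["smoking"]),
                alcohol=int(srow["alcohol"]),
                cyp3a_inhibitor=int(srow["cyp3a_inhibitor"]),
                cyp3a_inducer=int(srow["cyp3a_inducer"]),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{static_csv}: patient {pid}: {exc}") from exc

        dose_events = [
            DoseEvent(float(r.time_h), float(r.dose_mg))
            for r in dose_rows.itertuples()
        ]
        if max(d.time for d in dose_events) > window_hours:
            logger.warning(
                "excluding patient %s: dose beyond %g h window", pid, window_hours
            )
            continue

        obs_rows = troughs[troughs["patient_id"].astype(str) == pid]
        obs: list[TroughObservation] = []
        first_dose_t = min(d.time for d in dose_events)
        for r in obs_rows.itertuples():
            t, c = float(r.time_h), float(r.conc_ng_ml)
            if t <= first_dose_t:
                raise ValueError(
                    f"{trough_csv}: patient {pid}: trough at {t:g} h precedes the "
                    f"first dose at {first_dose_t:g} h"
                )
            if c < lloq:
                logger.warning(
                    "patient %s: dropping sub-LLOQ trough %.3g ng/mL at %g h",
                    pid, c, t,
                )
                continue
            if t > window_hours:
                logger.warning(
                    "patient %s: dropping trough at %g h beyond window", pid, t
                )
                continue
            obs.append(TroughObservation(t, c))
        if len(obs) < 2:
            logger.warning(
                "excluding patient %s: fewer than two usable trough measurements "
                "(%d found)", pid, len(obs),
            )
            continue

        lab_rows = labs[labs["patient_id"].astype(str) == pid]
        lab_series: dict[str, LabSeries] = {}
        for analyte, grp in lab_rows.groupby("analyte"):
            lab_series[str(analyte)] = LabSeries(
                str(analyte),
                grp["time_h"].to_numpy(float),
                grp["value"].to_numpy(float),
            )
        missing_labs = set(LAB_ANALYTES) - set(lab_series)
        if missing_labs:
            logger.warning(
                "excluding patient %s: missing lab series %s", pid, sorted(missing_labs)
            )
            continue

        records.append(PatientRecord(pid, dose_events, obs, lab_series, cov))
    return records


# --------------------------------------------------------------------------
# lab imputation


def impute_labs(series: LabSeries, query_times: Sequence[float]) -> np.ndarray:
    """Lab values at ``query_times``: linear interpolation between adjacent
    observations, nearest value carried forward/backward beyond the edges.
    An exact observation time returns the measured value."""
    q = np.asarray(query_times, dtype=float)
    return np.interp(q, series.times, series.values)


# --------------------------------------------------------------------------
# static encoding

_STATIC_CONTINUOUS = ("age", "height_cm", "weight_kg", "bmi", "bsa")
_STATIC_BINARY = ("smoking", "alcohol", "cyp3a_inhibitor", "cyp3a_inducer")

STATIC_FEATURE_NAMES: tuple[str, ...] = (
    _STATIC_CONTINUOUS
    + ("sex_male",)
    + _STATIC_BINARY
    + tuple(f"race_{lvl.lower().replace(' ', '_')}" for lvl in RACE_LEVELS)
)


def encode_static(
    s: StaticCovariates,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Numeric static-covariate vector: continuous fields (optionally
    z-scored with training-fold ``stats = (mean, std)`` over the
    continuous block), binary flags, and one-hot race."""
    cont = np.array([getattr(s, n) for n in _STATIC_CONTINUOUS], dtype=float)
    if stats is not None:
        mean, std = stats
        cont = (cont - mean) / np.where(std > 0, std, 1.0)
    binary = np.array(
        [1.0 if s.sex == "M" else 0.0]
        + [float(getattr(s, n)) for n in _STATIC_BINARY]
    )
    race = np.array([1.0 if s.race == lvl else 0.0 for lvl in RACE_LEVELS])
    return np.concatenate([cont, binary, race])


def fit_static_stats(patients: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Mean/std of the continuous static block over a training cohort."""
    mat = np.array(
        [[getattr(p.static, n) for n in _STATIC_CONTINUOUS] for p in patients]
    )
    return mat.mean(axis=0), mat.std(axis=0)


# --------------------------------------------------------------------------
# sequence construction (recurrent model)

SEQUENCE_STEP_FEATURES: tuple[str, ...] = (
    "dose_mg_since_prev",
    "dose_mg_last_admin",
    "trough_conc",
    "dt_since_prev",
    "time_since_first_dose",
) + LAB_ANALYTES

SEQUENCE_FEATURE_NAMES: tuple[str, ...] = SEQUENCE_STEP_FEATURES + STATIC_FEATURE_NAMES


def build_sequences(p: PatientRecord) -> list[SequenceSample]:
    """Prediction windows for the recurrent model.

    A patient with ``n`` troughs yields exactly ``n - 1`` samples; the
    first chronological trough is never a target.  Step ``j`` of a
    sample's feature matrix encodes history trough ``j``: the total dose
    administered since the previous step (mg), the observed trough, the
    elapsed time since the previous step, time since the first dose, the
    five time-varying labs imputed at the trough time, and the static
    encoding repeated at every step.
    """
    samples: list[SequenceSample] = []
    static_vec = encode_static(p.static)
    first_dose_t = p.doses[0].time
    for k in range(1, len(p.troughs)):
        target = p.troughs[k]
        steps = []
        prev_t = None
        for j in range(k):
            obs = p.troughs[j]
            window_start = first_dose_t - 1e-9 if prev_t is None else prev_t
            dose_mg = sum(
                d.amount for d in p.doses if window_start <= d.time < obs.time
            ) if prev_t is not None else sum(
                d.amount for d in p.doses if d.time < obs.time
            )
            dt = obs.time - (prev_t if prev_t is not None else first_dose_t)
            last_admin = max(
                (d for d in p.doses if d.time < obs.time), key=lambda d: d.time
            )
            labs = [p.lab_at(a, obs.time, cutoff=target.time) for a in LAB_ANALYTES]
            steps.append(
                np.concatenate((
                    [dose_mg, last_admin.amount, obs.concentration, dt,
                     obs.time - first_dose_t],
                    labs,
                    static_vec,
                ))
            )
            prev_t = obs.time
        samples.append(
            SequenceSample(
                patient_id=p.patient_id,
                target_index=k,
                features=np.vstack(steps),
                target_time=target.time,
                target_conc=target.concentration,
                doses=p.doses_until(target.time),
            )
        )
    return samples


def pad_batch(
    samples: Sequence[SequenceSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-pad a batch to its longest sequence.

    Returns ``(X, mask, lengths)`` with ``X`` of shape (B, T, F), ``mask``
    boolean (B, T) marking real steps, and integer ``lengths``.  Masked
    steps contribute nothing downstream: a model's output for a sample is
    identical whatever it is co-batched with.
    """
    if not samples:
        raise ValueError("empty batch")
    lengths = np.array([s.n_steps for s in samples], dtype=int)
    n_feat = samples[0].features.shape[1]
    T = int(lengths.max())
    X = np.zeros((len(samples), T, n_feat))
    mask = np.zeros((len(samples), T), dtype=bool)
    for i, s in enumerate(samples):
        X[i, : s.n_steps] = s.features
        mask[i, : s.n_steps] = True
    return X, mask, lengths


# --------------------------------------------------------------------------
# lag features (boosted model)

_LAG_BLOCK = ("remaining_mg", "trough_conc", "empirical_alpha") + LAB_ANALYTES

LAG_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"lag1_{n}" for n in _LAG_BLOCK)
    + tuple(f"lag2_{n}" for n in _LAG_BLOCK)
    + ("lag2_missing",)
    + ("time_after_transplant", "time_after_first_dose", "time_interval")
    + STATIC_FEATURE_NAMES
)

#: The purely data-driven ablation drops the two mechanism-derived lag
#: features (remaining drug amount, empirical alpha) and adds daily dose.
DD_LAG_FEATURE_NAMES: tuple[str, ...] = (
    ("daily_dose", "lag1_trough_conc")
    + tuple(f"lag1_{n}" for n in LAB_ANALYTES)
    + ("lag2_trough_conc",)
    + tuple(f"lag2_{n}" for n in LAB_ANALYTES)
    + ("lag2_missing",)
    + ("time_after_transplant", "time_after_first_dose", "time_interval")
    + STATIC_FEATURE_NAMES
)


def build_lag_features(
    p: PatientRecord,
    ke: float,
    *,
    transplant_offset_h: float = DEFAULT_TRANSPLANT_OFFSET_H,
) -> list[LagFeatureRow]:
    """Tabular rows for the boosted model, one per target trough.

    The lag-1 / lag-2 blocks are taken from the two most recent trough
    measurements before the target; when only one exists the lag-2 block
    is zero-filled and flagged.  The remaining drug amount and empirical
    alpha use the supplied elimination rate constant ``ke``.
    """
    rows: list[LagFeatureRow] = []
    static_vec = encode_static(p.static)
    first_dose_t = p.doses[0].time
    for k in range(1, len(p.troughs)):
        target = p.troughs[k]
        values: dict[str, float] = {}

        def lag_block(prefix: str, obs: TroughObservation | None) -> None:
            if obs is None:
                for n in _LAG_BLOCK:
                    values[f"{prefix}_{n}"] = 0.0
                return
            doses_before = p.doses_until(obs.time)
            rem = remaining_drug_amount(doses_before, obs.time, ke)
            values[f"{prefix}_remaining_mg"] = rem
            values[f"{prefix}_trough_conc"] = obs.concentration
            values[f"{prefix}_empirical_alpha"] = empirical_alpha(obs, doses_before, ke)
            for a in LAB_ANALYTES:
                values[f"{prefix}_{a}"] = p.lab_at(a, obs.time, cutoff=target.time)

        lag1 = p.troughs[k - 1]
        lag2 = p.troughs[k - 2] if k >= 2 else None
        lag_block("lag1", lag1)
        lag_block("lag2", lag2)
        values["lag2_missing"] = 0.0 if lag2 is not None else 1.0
        values["time_after_transplant"] = transplant_offset_h + (
            target.time - first_dose_t
        )
        values["time_after_first_dose"] = target.time - first_dose_t
        values["time_interval"] = target.time - lag1.time
        for name, v in zip(STATIC_FEATURE_NAMES, static_vec):
            values[name] = float(v)

        doses_until_target = p.doses_until(target.time)
        rows.append(
            LagFeatureRow(
                patient_id=p.patient_id,
                target_index=k,
                values=values,
                target_time=target.time,
                target_conc=target.concentration,
                remaining_at_target=remaining_drug_amount(
                    doses_until_target, target.time, ke
                ),
                daily_dose=sum(
                    d.amount
                    for d in p.doses
                    if target.time - 24.0 <= d.time < target.time
                ),
                doses=doses_until_target,
            )
        )
    return rows


def lag_matrix(
    rows: Sequence[LagFeatureRow], *, mechanism: bool = True
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack rows into a design matrix with the named column layout."""
    names = LAG_FEATURE_NAMES if mechanism else DD_LAG_FEATURE_NAMES
    X = np.zeros((len(rows), len(names)))
    for i, row in enumerate(rows):
        for j, n in enumerate(names):
            X[i, j] = row.daily_dose if n == "daily_dose" else row.values[n]
    return X, names
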