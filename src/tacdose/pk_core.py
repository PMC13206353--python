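"""Deterministic linear-pharmacokinetics engine for tacrolimus troughs.

One-compartment kinetics with first-order oral absorption and first-order
elimination, superposed over an arbitrary multiple-dose history.  Two
concentration models are provided:

* the full superposition model, parameterized by the absorption rate
  constant ``ka`` (1/h), elimination rate constant ``ke`` (1/h),
  bioavailability ``F`` and volume of distribution ``Vd`` (L);
* its trough-time simplification, in which the absorption exponential is
  dropped (valid because immediate-release tacrolimus is absorbed within
  0.5-2 h while troughs are drawn ~12 h post-dose) and the leading
  constant collapses into a single composite parameter
  ``alpha = F*ka/(Vd*(ka-ke)) ~= F/Vd``.

Unit conventions, fixed package-wide:

* dose amounts in mg, times in hours since the first tacrolimus dose,
  concentrations in ng/mL (= ug/L);
* the full model computes mg/L internally and multiplies by 1000
  (mg -> ug) to report ng/mL;
* ``alpha`` therefore carries units of (ng/mL) per mg of remaining drug,
  i.e. the mg->ug factor is absorbed into alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DoseEvent",
    "TroughObservation",
    "PKParams",
    "FullPKParams",
    "KE_LOWER",
    "KE_UPPER",
    "MG_TO_NG_PER_ML",
    "concentration_full",
    "remaining_drug_amount",
    "concentration_simplified",
    "empirical_alpha",
    "composite_alpha",
]

#: Physiologically plausible elimination-rate band for adult kidney
#: transplant recipients (1/h); the constrained model head maps into it.
KE_LOWER = 0.017
KE_UPPER = 0.17

#: mg -> ug conversion so that mg/L is reported as ng/mL.
MG_TO_NG_PER_ML = 1000.0

_EPS_AMOUNT = 1e-9


@dataclass(frozen=True)
class DoseEvent:
    """One administered oral dose.

    Parameters
    ----------
    time : float
        Hours since the first dose (>= 0, finite).
    amount : float
        Dose in mg (> 0).
    """

    time: float
    amount: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"dose time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.amount) or self.amount <= 0:
            raise ValueError(f"dose amount must be > 0 mg, got {self.amount}")


@dataclass(frozen=True)
class TroughObservation:
    """One therapeutic-drug-monitoring trough measurement.

    ``time`` is hours since the first dose; ``concentration`` is the
    whole-blood level in ng/mL (> 0; sub-LLOQ values are handled upstream).
    """

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValueError(f"trough time must be finite, got {self.time}")
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise ValueError(
                f"trough concentration must be > 0 ng/mL, got {self.concentration}"
            )


@dataclass(frozen=True)
class PKParams:
    """Composite parameters of the simplified trough model.

    ``alpha`` maps remaining drug amount (mg) to concentration (ng/mL);
    ``ke`` is the effective elimination rate constant (1/h).  The
    constrained model head guarantees ``ke`` in [0.017, 0.17]; the
    dataclass itself only requires positivity so that externally supplied
    values (e.g. population estimates) are representable.
    """

    alpha: float
    ke: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not np.isfinite(self.ke) or self.ke <= 0:
            raise ValueError(f"ke must be > 0 1/h, got {self.ke}")


@dataclass(frozen=True)
class FullPKParams:
    """Structural parameters of the full first-order absorption model."""

    ka: float
    ke: float
    F: float
    Vd: float

    def __post_init__(self) -> None:
        if self.ke <= 0:
            raise ValueError(f"ke must be > 0 1/h, got {self.ke}")
        if self.ka <= self.ke:
            raise ValueError(
                f"ka ({self.ka}) must exceed ke ({self.ke}); the first-order "
                "oral superposition expression is invalid otherwise"
            )
        if not (0 < self.F <= 1):
            raise ValueError(f"F must be in (0, 1], got {self.F}")
        if self.Vd <= 0:
            raise ValueError(f"Vd must be > 0 L, got {self.Vd}")


def composite_alpha(p: FullPKParams) -> float:
    """Composite exposure parameter alpha = F*ka/(Vd*(ka-ke)), in
    (ng/mL)/mg (the mg->ug factor is included)."""
    return MG_TO_NG_PER_ML * p.F * p.ka / (p.Vd * (p.ka - p.ke))


def _dose_arrays(doses: Sequence[DoseEvent], t: float) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([d.time for d in doses], dtype=float)
    amounts = np.asarray([d.amount for d in doses], dtype=float)
    if times.size and times.max() > t:
        raise ValueError(
            f"dose at t={times.max():g} h lies after evaluation time t={t:g} h"
        )
    return times, amounts


def concentration_full(doses: Sequence[DoseEvent], t: float, p: FullPKParams) -> float:
    """Concentration (ng/mL) at time ``t`` under full superposition.

    C(t) = sum_i  F*ka/(Vd*(ka-ke)) * D_i * (e^{-ke(t-t_i)} - e^{-ka(t-t_i)}),
    with D_i in mg and the result scaled mg/L -> ng/mL (x1000).

    Raises ``ValueError`` if any dose lies after ``t``.
    """
    times, amounts = _dose_arrays(doses, t)
    if times.size == 0:
        return 0.0
    dt = t - times
    coef = p.F * p.ka / (p.Vd * (p.ka - p.ke))
    conc_mg_per_l = coef * np.sum(amounts * (np.exp(-p.ke * dt) - np.exp(-p.ka * dt)))
    return float(MG_TO_NG_PER_ML * conc_mg_per_l)


def remaining_drug_amount(doses: Sequence[DoseEvent], t: float, ke: float) -> float:
    """Superposed undeliminated dose mass (mg) at time ``t``:
    sum_i D_i * e^{-ke (t - t_i)}.

    ``ke = 0`` is permitted (no elimination; returns the total dose).
    """
    if ke < 0:
        raise ValueError(f"ke must be >= 0, got {ke}")
    times, amounts = _dose_arrays(doses, t)
    if times.size == 0:
        return 0.0
    return float(np.sum(amounts * np.exp(-ke * (t - times))))


def concentration_simplified(doses: Sequence[DoseEvent], t: float, p: PKParams) -> float:
    """Trough-time concentration (ng/mL): alpha x remaining drug amount.

    Exactly linear in any uniform scaling of the dose amounts.
    """
    return p.alpha * remaining_drug_amount(doses, t, p.ke)


def empirical_alpha(
    trough: TroughObservation, doses: Sequence[DoseEvent], ke: float
) -> float:
    """Empirical composite parameter: observed trough divided by the
    remaining drug amount at the trough time.

    Inverts :func:`concentration_simplified` exactly when ``ke`` matches
    the value that generated the trough.  Raises ``ValueError`` when the
    remaining amount is (numerically) zero.
    """
    amount = remaining_drug_amount(doses, trough.time, ke)
    if amount <= _EPS_AMOUNT:
        raise ValueError(
            f"remaining drug amount {amount:g} mg at t={trough.time:g} h is too "
            "small to define an empirical alpha"
        )
    return trough.concentration / amount
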