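"""Therapy concentration functions and clinical parameter scaling.

Drug exposure is modeled with one-compartment IV kinetics: each bolus dose
decays exponentially with the elimination constant k_e = ln 2 / t_half,
and overlapping doses superpose.  Concentrations are normalized so 1.0 is
the peak of a single 1000 mg obinutuzumab dose (3.76 umol/L, kept as
metadata); sweeps scale the entire schedule by a multiplier, so the
concentration axis stays dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CloneState, GrowthParams, InteractionParams, ModelParams

__all__ = [
    "DoseSchedule",
    "ConstantTherapy",
    "ClinicalParams",
    "doubling_time_to_rate",
    "rate_to_doubling_time",
    "halflife_to_elimination",
    "concentration_at",
    "obinutuzumab_schedule",
    "relative_potency",
    "scale_to_clinical",
    "logistic_rate_between",
    "OBINUTUZUMAB_HALFLIFE_DAYS",
    "OBINUTUZUMAB_PEAK_UMOL_L",
]

OBINUTUZUMAB_HALFLIFE_DAYS = 28.4
OBINUTUZUMAB_PEAK_UMOL_L = 3.76  # peak of one 1000 mg dose


def doubling_time_to_rate(t_double: float) -> float:
    """First-order growth rate (day^-1) from a doubling time in days."""
    if t_double <= 0:
        raise ValueError("doubling time must be > 0")
    return math.log(2.0) / t_double


def rate_to_doubling_time(rate: float) -> float:
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return math.log(2.0) / rate


def halflife_to_elimination(t_half: float) -> float:
    """Elimination constant (day^-1) from a plasma half-life in days."""
    if t_half <= 0:
        raise ValueError("half-life must be > 0")
    return math.log(2.0) / t_half


class ConstantTherapy:
    """A constant normalized concentration (the simplest f(t))."""

    breakpoints: tuple[float, ...] = ()

    def __init__(self, level: float = 1.0):
        self.level = float(level)

    def __call__(self, t: float) -> float:
        return self.level


@dataclass(frozen=True)
class DoseSchedule:
    """Bolus doses with shared first-order elimination.

    ``dose_amounts`` are in normalized units (1.0 = one 1000 mg dose).
    Callable: evaluates the superposed concentration at time t.
    """

    dose_days: tuple[float, ...]
    dose_amounts: tuple[float, ...]
    k_e: float
    c_ref_umol_l: float = OBINUTUZUMAB_PEAK_UMOL_L

    def __post_init__(self) -> None:
        if len(self.dose_days) != len(self.dose_amounts):
            raise ValueError("dose_days and dose_amounts must align")
        if self.k_e <= 0:
            raise ValueError("k_e must be > 0")
        if any(a <= 0 for a in self.dose_amounts):
            raise ValueError("dose amounts must be > 0")
        if any(b < a for a, b in zip(self.dose_days, self.dose_days[1:])):
            raise ValueError("dose_days must be non-decreasing")

    def __call__(self, t: float) -> float:
        days = np.asarray(self.dose_days)
        amounts = np.asarray(self.dose_amounts)
        given = days <= t
        if not given.any():
            return 0.0
        return float(np.sum(amounts[given] * np.exp(-self.k_e * (t - days[given]))))

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return self.dose_days

    def scaled(self, factor: float) -> "DoseSchedule":
        return replace(
            self, dose_amounts=tuple(a * factor for a in self.dose_amounts)
        )

    def concatenate(self, other: "DoseSchedule") -> "DoseSchedule":
        if not math.isclose(self.k_e, other.k_e):
            raise ValueError("schedules must share the elimination constant")
        pairs = sorted(
            list(zip(self.dose_days, self.dose_amounts))
            + list(zip(other.dose_days, other.dose_amounts))
        )
        return DoseSchedule(
            tuple(p[0] for p in pairs), tuple(p[1] for p in pairs), self.k_e
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.dose_days, "amount": self.dose_amounts})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def concentration_at(schedule: DoseSchedule, t: float) -> float:
    """Superposed normalized concentration at day ``t`` (0 before any dose)."""
    return schedule(t)


def obinutuzumab_schedule() -> DoseSchedule:
    """The trial dosing pattern used for the clinical simulations.

    Unit (1000 mg) doses on days 0, 7 and 14 of the first 21-day cycle,
    then one unit dose at the start of each of cycles 2-8 (days 21, 42,
    ..., 147); treatment stops at day 168.  Elimination constant
    ln 2 / 28.4 days ~= 0.02441 day^-1.
    """
    loading = (0.0, 7.0, 14.0)
    maintenance = tuple(21.0 * i for i in range(1, 8))
    days = loading + maintenance
    return DoseSchedule(
        dose_days=days,
        dose_amounts=(1.0,) * len(days),
        k_e=halflife_to_elimination(OBINUTUZUMAB_HALFLIFE_DAYS),
    )


def relative_potency(
    prolif_resistant_pct: float, prolif_sensitive_pct: float
) -> float:
    """Potency ratio a_R / a_G from residual proliferation percentages.

    A clone proliferating at 75% of its untreated level under saturating
    drug is killed one quarter as effectively as a clone whose
    proliferation drops to 0%.
    """
    for name, v in (
        ("prolif_resistant_pct", prolif_resistant_pct),
        ("prolif_sensitive_pct", prolif_sensitive_pct),
    ):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100]")
    if prolif_sensitive_pct == 100.0:
        raise ValueError("sensitive proliferation of 100% leaves the ratio undefined")
    return (100.0 - prolif_resistant_pct) / (100.0 - prolif_sensitive_pct)


@dataclass(frozen=True)
class ClinicalParams:
    """In-vitro constants rescaled to human tumor values."""

    k_sensitive: float
    k_resistant: float
    capacity: float
    c_gr: float
    c_rg: float
    m: float
    weighted: bool
    init: CloneState

    def growth(self) -> GrowthParams:
        return GrowthParams(self.k_sensitive, self.k_resistant, self.capacity)

    def interaction(self) -> InteractionParams | None:
        if self.c_gr == 0.0 and self.c_rg == 0.0:
            return None
        return InteractionParams(self.c_gr, self.c_rg, m=self.m, weighted=self.weighted)

    def to_model_params(self, therapy=None, therapy_fn=None) -> ModelParams:
        return ModelParams(self.growth(), self.interaction(), therapy, therapy_fn)


def scale_to_clinical(
    vitro: ModelParams,
    k_sensitive_clinical: float,
    capacity_clinical: float = float(2**40),
    init_total: float = 1e9,
    resistant_fraction: float = 0.1,
) -> ClinicalParams:
    """Rescale culture-calibrated constants to tumor scale.

    The scale factor s = k_G_clin / k_G_vitro stretches time; the capacity
    swap stretches cell number.  Constants are rescaled so the
    nondimensionalized dynamics (populations in units of N, time in units
    of 1/k_G) are preserved: day^-1 constants (growth rates, weighted
    interaction constants) multiply by s, and cell^-1 day^-1 constants
    (unweighted interaction) multiply by s * N_vitro / N_clin.  Therapy
    potencies are not rescaled -- they stay normalized per unit of the
    dimensionless concentration axis.
    """
    if k_sensitive_clinical <= 0 or capacity_clinical <= 0 or init_total <= 0:
        raise ValueError("clinical constants must be > 0")
    if not 0.0 <= resistant_fraction <= 1.0:
        raise ValueError("resistant_fraction must be in [0, 1]")
    s = k_sensitive_clinical / vitro.growth.k_sensitive
    if s <= 0:
        raise ValueError("nonpositive rate scale")

    inter = vitro.interaction
    if inter is None:
        c_gr = c_rg = 0.0
        m, weighted = 1.0, True
    elif inter.weighted:
        c_gr, c_rg = inter.c_gr * s, inter.c_rg * s
        m, weighted = inter.m, True
    else:
        cell_scale = vitro.growth.capacity / capacity_clinical
        c_gr, c_rg = inter.c_gr * s * cell_scale, inter.c_rg * s * cell_scale
        m, weighted = inter.m, False

    return ClinicalParams(
        k_sensitive=k_sensitive_clinical,
        k_resistant=vitro.growth.k_resistant * s,
        capacity=capacity_clinical,
        c_gr=c_gr,
        c_rg=c_rg,
        m=m,
        weighted=weighted,
        init=CloneState(
            init_total * (1.0 - resistant_fraction), init_total * resistant_fraction
        ),
    )


def logistic_rate_between(
    n_start: float, n_end: float, capacity: float, duration: float
) -> float:
    """Logistic rate connecting two population sizes over a known duration.

    Inverts the closed-form logistic; the duration must be supplied
    explicitly -- two sizes alone do not determine a rate.
    """
    if not (0 < n_start < capacity and 0 < n_end < capacity):
        raise ValueError("populations must lie strictly between 0 and the capacity")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    odds = (n_end * (capacity - n_start)) / (n_start * (capacity - n_end))
    return math.log(odds) / duration
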