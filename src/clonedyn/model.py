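"""Right-hand sides of the two-clone growth model.

The model tracks an antibody-sensitive clone (G) and an antibody-resistant
clone (R) sharing one logistic carrying capacity.  Three layers can be
stacked on the plain logistic core:

* an interclonal interaction term, either the classic Lotka--Volterra
  product form ``C * G * R`` or a cooperativity-weighted form
  ``C * R * G**m / (G + R)**m`` whose exponent ``m`` sets which mixture
  maximizes the interaction (resistant fraction ``1 / (1 + m)``);
* an antibody kill term driven by a concentration function ``f(t)``,
  either zero-order (``-a * f(t)``, removal independent of population
  size) or first-order (``-a * f(t) * X``, per-cell kill).

Everything here is a pure derivative evaluation; integration lives in
:mod:`clonedyn.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CloneState",
    "GrowthParams",
    "InteractionParams",
    "TherapyParams",
    "ModelParams",
    "ZERO_ORDER",
    "FIRST_ORDER",
    "logistic_rhs",
    "interaction_term",
    "full_rhs",
    "rhs_function",
    "params_to_dict",
    "params_from_dict",
    "load_config",
    "save_config",
]

ZERO_ORDER = "zero_order"
FIRST_ORDER = "first_order"


@dataclass(frozen=True)
class CloneState:
    """Instantaneous (sensitive, resistant) cell numbers."""

    sensitive: float
    resistant: float

    def __post_init__(self) -> None:
        for name in ("sensitive", "resistant"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} count must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} count must be >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.sensitive + self.resistant

    def as_array(self) -> np.ndarray:
        return np.array([self.sensitive, self.resistant], dtype=float)

    @staticmethod
    def coerce(value: "CloneState | Sequence[float]") -> "CloneState":
        if isinstance(value, CloneState):
            return value
        g, r = value
        return CloneState(float(g), float(r))


@dataclass(frozen=True)
class GrowthParams:
    """Per-clone logistic growth rates (day^-1) and the shared capacity (cells)."""

    k_sensitive: float
    k_resistant: float
    capacity: float

    def __post_init__(self) -> None:
        for name in ("k_sensitive", "k_resistant", "capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class InteractionParams:
    """Interclonal coupling constants.

    ``c_gr`` modifies the sensitive clone's derivative, ``c_rg`` the
    resistant clone's.  In the unweighted (product) form the constants
    carry units cell^-1 day^-1; in the weighted form the term is degree-1
    homogeneous in cell number, so the constants carry units day^-1.  The
    constants are stored exactly as supplied -- no rescaling between the
    two variants.
    """

    c_gr: float
    c_rg: float
    m: float = 1.0
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("cooperativity exponent m must be >= 0")


@dataclass(frozen=True)
class TherapyParams:
    """Antibody potencies against each clone and the kill-term order.

    ``zero_order`` removes ``a * f(t)`` cells/day regardless of population
    size (the states are clamped at zero, so extinction is absorbing).
    ``first_order`` removes ``a * f(t) * X`` -- a per-cell kill rate, the
    form used by the therapy and clinical sweeps.
    """

    a_sensitive: float
    a_resistant: float
    death_order: str = ZERO_ORDER

    def __post_init__(self) -> None:
        if self.a_sensitive < 0 or self.a_resistant < 0:
            raise ValueError("potencies must be >= 0")
        if self.death_order not in (ZERO_ORDER, FIRST_ORDER):
            raise ValueError(f"unknown death_order {self.death_order!r}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: growth core plus optional interaction and therapy."""

    growth: GrowthParams
    interaction: InteractionParams | None = None
    therapy: TherapyParams | None = None
    therapy_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if (self.therapy is None) != (self.therapy_fn is None):
            raise ValueError(
                "therapy parameters and the concentration function f(t) "
                "must be supplied together"
            )


def logistic_rhs(state: CloneState | Sequence[float], growth: GrowthParams) -> tuple[float, float]:
    """Plain shared-capacity logistic derivatives (cells/day).

    Totals above the capacity simply yield negative derivatives.
    """
    state = CloneState.coerce(state)
    crowd = 1.0 - state.total / growth.capacity
    return (
        growth.k_sensitive * state.sensitive * crowd,
        growth.k_resistant * state.resistant * crowd,
    )


def interaction_term(
    state: CloneState | Sequence[float],
    c: float,
    m: float = 1.0,
    weighted: bool = False,
) -> float:
    """One clone's interaction contribution (cells/day).

    Unweighted: ``c * G * R``.  Weighted: ``c * R * G**m / (G + R)**m``,
    defined as 0 for an empty culture (no cells, no interaction).
    """
    state = CloneState.coerce(state)
    g, r = state.sensitive, state.resistant
    if not weighted:
        return c * g * r
    total = g + r
    if total == 0.0:
        return 0.0
    return c * r * (g / total) ** m


def _death_terms(
    g: float, r: float, t: float, therapy: TherapyParams, therapy_fn: Callable[[float], float]
) -> tuple[float, float]:
    conc = float(therapy_fn(t))
    if therapy.death_order == FIRST_ORDER:
        return therapy.a_sensitive * conc * g, therapy.a_resistant * conc * r
    return therapy.a_sensitive * conc, therapy.a_resistant * conc


def full_rhs(
    t: float, state: CloneState | Sequence[float], params: ModelParams
) -> tuple[float, float]:
    """Complete derivative pair: logistic + interaction - antibody kill.

    Negative coordinates are clamped to zero before evaluation, and a
    clamped coordinate whose derivative would be negative reports zero
    (extinction is absorbing).
    """
    raw = CloneState.coerce(state) if isinstance(state, CloneState) else state
    if isinstance(raw, CloneState):
        y0, y1 = raw.sensitive, raw.resistant
    else:
        y0, y1 = float(raw[0]), float(raw[1])
    g, r = max(y0, 0.0), max(y1, 0.0)

    growth = params.growth
    crowd = 1.0 - (g + r) / growth.capacity
    dg = growth.k_sensitive * g * crowd
    dr = growth.k_resistant * r * crowd

    inter = params.interaction
    if inter is not None:
        dg += interaction_term((g, r), inter.c_gr, inter.m, inter.weighted)
        dr += interaction_term((g, r), inter.c_rg, inter.m, inter.weighted)

    if params.therapy is not None:
        if params.therapy_fn is None:  # pragma: no cover - blocked by ModelParams
            raise ValueError("therapy requested but no concentration function")
        kg, kr = _death_terms(g, r, t, params.therapy, params.therapy_fn)
        dg -= kg
        dr -= kr

    if y0 <= 0.0 and dg < 0.0:
        dg = 0.0
    if y1 <= 0.0 and dr < 0.0:
        dr = 0.0
    return dg, dr


def rhs_function(params: ModelParams) -> Callable[[float, np.ndarray], list[float]]:
    """Compile ``params`` into a fast ``f(t, y)`` closure for the integrator.

    Semantics match :func:`full_rhs` exactly; this avoids per-call
    dataclass construction inside `solve_ivp`.
    """
    growth = params.growth
    k_g, k_r, cap = growth.k_sensitive, growth.k_resistant, growth.capacity
    inter = params.interaction
    therapy, fn = params.therapy, params.therapy_fn

    if inter is None:
        c_gr = c_rg = 0.0
        weighted, m = False, 1.0
    else:
        c_gr, c_rg, weighted, m = inter.c_gr, inter.c_rg, inter.weighted, inter.m

    zero_order = therapy is not None and therapy.death_order == ZERO_ORDER

    def rhs(t: float, y: np.ndarray) -> list[float]:
        # plain floats: overflow goes to inf quietly and surfaces as a
        # blow-up in the integrator rather than as numpy warnings
        g = float(y[0]) if y[0] > 0.0 else 0.0
        r = float(y[1]) if y[1] > 0.0 else 0.0
        crowd = 1.0 - (g + r) / cap
        dg = k_g * g * crowd
        dr = k_r * r * crowd
        if inter is not None:
            if weighted:
                total = g + r
                w = (g / total) ** m if total > 0.0 else 0.0
                dg += c_gr * r * w
                dr += c_rg * r * w
            else:
                prod = g * r
                dg += c_gr * prod
                dr += c_rg * prod
        if therapy is not None:
            conc = float(fn(t))
            if zero_order:
                dg -= therapy.a_sensitive * conc
                dr -= therapy.a_resistant * conc
            else:
                dg -= therapy.a_sensitive * conc * g
                dr -= therapy.a_resistant * conc * r
        if y[0] <= 0.0 and dg < 0.0:
            dg = 0.0
        if y[1] <= 0.0 and dr < 0.0:
            dr = 0.0
        return [dg, dr]

    return rhs


# --- flat key-value config serialization -----------------------------------
#
# Keys: k_G, k_R, N, C_GR, C_RG, m, weighted, a_G, a_R, death_order.
# Absent interaction/therapy blocks mean "absent".

_GROWTH_KEYS = ("k_G", "k_R", "N")
_INTER_KEYS = ("C_GR", "C_RG")
_THERAPY_KEYS = ("a_G", "a_R")


def params_to_dict(params: ModelParams) -> dict:
    d: dict = {
        "k_G": params.growth.k_sensitive,
        "k_R": params.growth.k_resistant,
        "N": params.growth.capacity,
    }
    if params.interaction is not None:
        d.update(
            C_GR=params.interaction.c_gr,
            C_RG=params.interaction.c_rg,
            m=params.interaction.m,
            weighted=params.interaction.weighted,
        )
    if params.therapy is not None:
        d.update(
            a_G=params.therapy.a_sensitive,
            a_R=params.therapy.a_resistant,
            death_order=params.therapy.death_order,
        )
    return d


def params_from_dict(
    d: Mapping, therapy_fn: Callable[[float], float] | None = None
) -> ModelParams:
    """Rebuild :class:`ModelParams` from a flat mapping.

    A config with therapy keys needs ``therapy_fn`` supplied by the caller;
    concentration functions are built programmatically (see
    :mod:`clonedyn.pharm`), not serialized.
    """
    missing = [k for k in _GROWTH_KEYS if k not in d]
    if missing:
        raise KeyError(f"config missing growth keys: {missing}")
    growth = GrowthParams(float(d["k_G"]), float(d["k_R"]), float(d["N"]))

    interaction = None
    if any(k in d for k in _INTER_KEYS):
        interaction = InteractionParams(
            c_gr=float(d.get("C_GR", 0.0)),
            c_rg=float(d.get("C_RG", 0.0)),
            m=float(d.get("m", 1.0)),
            weighted=bool(d.get("weighted", False)),
        )

    therapy = None
    if any(k in d for k in _THERAPY_KEYS):
        therapy = TherapyParams(
            a_sensitive=float(d.get("a_G", 0.0)),
            a_resistant=float(d.get("a_R", 0.0)),
            death_order=str(d.get("death_order", ZERO_ORDER)),
        )
        if therapy_fn is None:
            raise ValueError(
                "config specifies therapy potencies; pass therapy_fn to attach "
                "a concentration function"
            )
    return ModelParams(growth, interaction, therapy, therapy_fn if therapy else None)


def load_config(path, therapy_fn: Callable[[float], float] | None = None) -> ModelParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return params_from_dict(d, therapy_fn=therapy_fn)


def save_config(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)
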