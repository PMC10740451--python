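"""Scripted computational experiments over the two-clone model.

Each suite reproduces one family of simulations as a configured, seedable
run returning tidy tables: the interaction taxonomy (which coupling signs
produce divergent, convergent, extinction or bistable steady states), the
constant-therapy concentration sweeps per cooperativity exponent, and the
clinical dosing sweeps at tumor scale.  The therapy and clinical suites
default to this package's own anchor-calibrated interaction constants, so
their outputs are qualitative reproductions (shift classes and persistence
patterns), not numeric threshold matches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    FIRST_ORDER,
    CloneState,
    GrowthParams,
    InteractionParams,
    ModelParams,
    TherapyParams,
)
from .pharm import ConstantTherapy, doubling_time_to_rate, obinutuzumab_schedule, scale_to_clinical
from .rates import calibrate_to_anchor_rates
from .simulate import (
    EXTINCTION_FLOOR,
    SweepResult,
    concentration_sweep,
    steady_state,
    sweep_to_frame,
)

__all__ = [
    "TAXONOMY_CONSTANTS",
    "run_taxonomy_suite",
    "classify_outcomes",
    "run_therapy_suite",
    "run_clinical_suite",
    "write_manifest",
]

#: Unweighted interaction constants (cell^-1 day^-1) defining the taxonomy.
TAXONOMY_CONSTANTS: dict[str, tuple[float, float] | None] = {
    "none": None,
    "parasitic": (-1e-7, 1e-7),
    "competitive": (-1e-7, -1e-7),
    "mutualistic": (1e-6, 1e-6),
}

TAXONOMY_GROWTH = GrowthParams(1.0, 0.5, 6e5)
DEFAULT_TAXONOMY_FRACTIONS = (0.1, 0.25, 0.5, 0.75, 0.9)

# In-vitro base for the calibrated therapy models.
INVITRO_GROWTH = GrowthParams(1.069, 0.4695, 6e5)

SLOW_DOUBLING_DAYS = 29.0
FAST_DOUBLING_DAYS = 14.0


def classify_outcomes(
    end_states: np.ndarray,
    *,
    extinct_below: float = EXTINCTION_FLOOR,
    axis_share: float = 0.01,
    cluster_rtol: float = 0.01,
) -> str:
    """Label the steady-state pattern of mixed-culture end states.

    ``extinction_of_G``: the sensitive clone is below the extinction cutoff
    in every mixture.  ``convergent``: all end states coincide (within
    ``cluster_rtol`` relative distance).  ``bistable``: every end state
    hugs one of the single-clone axes and both axes are represented.
    Anything else is ``divergent`` (a continuum of mixture-dependent
    interior states).
    """
    states = np.asarray(end_states, dtype=float)
    totals = states.sum(axis=1)
    if np.all(states[:, 0] < extinct_below):
        return "extinction_of_G"
    scale = totals.max()
    if np.all(np.linalg.norm(states - states[0], axis=1) <= cluster_rtol * scale):
        return "convergent"
    minor_share = states.min(axis=1) / np.maximum(totals, 1.0)
    if np.all(minor_share < axis_share):
        on_g_axis = states[:, 0] > states[:, 1]
        if on_g_axis.any() and (~on_g_axis).any():
            return "bistable"
    return "divergent"


def run_taxonomy_suite(
    fractions: Sequence[float] = DEFAULT_TAXONOMY_FRACTIONS,
    total_init: float = 1e5,
    t_max: float = 1000.0,
    growth: GrowthParams = TAXONOMY_GROWTH,
    constants: Mapping[str, tuple[float, float] | None] = TAXONOMY_CONSTANTS,
) -> pd.DataFrame:
    """Steady states per interaction type across initial mixtures.

    Returns one row per (interaction type, fraction) with the long-run
    state and a per-type classification column.
    """
    rows = []
    for name, c in constants.items():
        inter = None if c is None else InteractionParams(c[0], c[1], weighted=False)
        params = ModelParams(growth, inter)
        ends = []
        for f in fractions:
            init = CloneState(total_init * (1.0 - f), total_init * f)
            res = steady_state(params, init, t_max=t_max)
            ends.append(res.state.as_array())
            rows.append(
                {
                    "interaction": name,
                    "fraction_resistant": f,
                    "end_sensitive": res.state.sensitive,
                    "end_resistant": res.state.resistant,
                    "converged": res.converged,
                }
            )
        label = classify_outcomes(np.array(ends))
        for row in rows[-len(fractions):]:
            row["classification"] = label
    return pd.DataFrame(rows)


def run_therapy_suite(
    m_values: Sequence[float] = (0.5, 1.0, 2.0, 3.0),
    constants: Mapping[float, tuple[float, float]] | None = None,
    grid: Sequence[float] | None = None,
    init: tuple[float, float] = (5e4, 5e4),
    t_end: float = 1000.0,
    growth: GrowthParams = INVITRO_GROWTH,
) -> dict[float, SweepResult]:
    """Constant-therapy concentration sweeps per cooperativity exponent.

    Potencies are normalized to a_G = 1 and a_R = 1/4 with first-order
    (per-cell) kill; the antibody is present at a constant normalized
    concentration given by each grid value.  Interaction constants default
    to the anchor-rate calibration per exponent.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    results: dict[float, SweepResult] = {}
    for m in m_values:
        c_gr, c_rg = (
            constants[m] if constants is not None else calibrate_to_anchor_rates(float(m))
        )
        params = ModelParams(
            growth,
            InteractionParams(c_gr, c_rg, m=float(m), weighted=True),
            TherapyParams(1.0, 0.25, death_order=FIRST_ORDER),
            ConstantTherapy(1.0),
        )
        results[float(m)] = concentration_sweep(
            params, grid, CloneState(*init), t_end
        )
    return results


def therapy_suite_frame(results: Mapping[float, SweepResult]) -> pd.DataFrame:
    frames = []
    for m, res in results.items():
        df = sweep_to_frame(res)
        df.insert(0, "m", m)
        df["threshold"] = res.threshold
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_clinical_suite(
    growth_case: str = "slow",
    m_values: Sequence[float | None] = (None, 1.0, 2.0),
    grid: Sequence[float] | None = None,
    t_end: float = 1500.0,
    vitro_growth: GrowthParams = INVITRO_GROWTH,
) -> pd.DataFrame:
    """Multi-dose clinical sweeps at tumor scale.

    ``growth_case`` picks the sensitive clinical growth rate from the
    29-day (slow) or 14-day (fast) doubling time.  Each scenario scales the
    in-vitro model to a 10^9-cell tumor (9:1 sensitive:resistant) with
    capacity 2^40 cells, applies the obinutuzumab dosing schedule times a
    concentration multiplier, and reports the day-1500 counts.
    """
    if growth_case not in ("slow", "fast"):
        raise ValueError("growth_case must be 'slow' or 'fast'")
    t_double = SLOW_DOUBLING_DAYS if growth_case == "slow" else FAST_DOUBLING_DAYS
    k_clin = doubling_time_to_rate(t_double)
    if grid is None:
        hi = 0.3 if growth_case == "slow" else 0.6
        grid = np.round(np.linspace(0.0, hi, 16), 10)
    grid = np.asarray(grid, dtype=float)
    schedule = obinutuzumab_schedule()

    rows = []
    for m in m_values:
        if m is None:
            vitro = ModelParams(vitro_growth)
        else:
            c_gr, c_rg = calibrate_to_anchor_rates(float(m))
            vitro = ModelParams(
                vitro_growth, InteractionParams(c_gr, c_rg, m=float(m), weighted=True)
            )
        clin = scale_to_clinical(vitro, k_clin)
        params = clin.to_model_params(
            therapy=TherapyParams(1.0, 0.25, death_order=FIRST_ORDER),
            therapy_fn=schedule,
        )
        sweep = concentration_sweep(params, grid, clin.init, t_end)
        for conc, (g, r) in zip(grid, sweep.end_states):
            rows.append(
                {
                    "growth_case": growth_case,
                    "m": np.nan if m is None else float(m),
                    "interaction": "none" if m is None else f"m={m:g}",
                    "concentration": conc,
                    "end_sensitive": g,
                    "end_resistant": r,
                    "shift_type": sweep.shift_type,
                }
            )
    return pd.DataFrame(rows)


def write_manifest(path, config: Mapping, solver: Mapping | None = None) -> str:
    """Record a run's inputs and a content hash for bit-identical reruns."""
    payload = {
        "config": {k: config[k] for k in sorted(config)},
        "solver": dict(solver or {"method": "LSODA", "rtol": 1e-8, "atol": 1e-2}),
    }
    text = json.dumps(payload, sort_keys=True, default=str)
    digest = hashlib.sha256(text.encode()).hexdigest()
    payload["sha256"] = digest
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return digest
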