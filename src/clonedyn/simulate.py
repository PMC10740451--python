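"""Time integration, steady states, phase portraits and concentration sweeps.

The integrator is SciPy's adaptive, stiffness-switching LSODA with
rtol=1e-8 and atol=1e-2 cells; these settings reproduce the closed-form
logistic to six digits.  Cell counts are clamped nonnegative, and an
optional absorbing floor treats a clone that falls below one cell as
extinct for the rest of the run (sub-cell fractions are unphysical and
would otherwise "regrow" once therapy wanes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import CloneState, ModelParams, full_rhs, rhs_function

__all__ = [
    "Trajectory",
    "SteadyStateResult",
    "PhasePortrait",
    "SweepResult",
    "SimulationBlowUp",
    "ScaledTherapy",
    "simulate",
    "steady_state",
    "phase_portrait",
    "gr_ratio_series",
    "concentration_sweep",
    "EXTINCTION_FLOOR",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-2  # cells
EXTINCTION_FLOOR = 1.0  # one cell


class SimulationBlowUp(RuntimeError):
    """Raised when the state leaves the finite range (e.g. runaway mutualism)."""

    def __init__(self, t: float, message: str | None = None):
        self.t = t
        super().__init__(message or f"non-finite state at t = {t:g} days")


@dataclass
class Trajectory:
    """Time-indexed (sensitive, resistant) states from one integration."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    params: ModelParams

    @property
    def sensitive(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def resistant(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def total(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def final_state(self) -> CloneState:
        return CloneState(*self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.times, "sensitive": self.sensitive, "resistant": self.resistant}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SteadyStateResult:
    state: CloneState
    converged: bool
    t_reached: float | None = None


@dataclass
class PhasePortrait:
    fractions: np.ndarray
    trajectories: list[Trajectory]
    marks_mid: np.ndarray  # states at t_mark, shape (n, 2)
    marks_end: np.ndarray  # states at t_end


@dataclass
class SweepResult:
    concentrations: np.ndarray
    end_states: np.ndarray  # shape (n, 2)
    shift_type: str  # 'abrupt' | 'gradual' | 'none'
    threshold: float | None  # smallest concentration with sensitive extinction


class ScaledTherapy:
    """A concentration function multiplied by a scalar, breakpoints preserved."""

    def __init__(self, fn: Callable[[float], float], scale: float):
        self.fn = fn
        self.scale = float(scale)

    def __call__(self, t: float) -> float:
        return self.scale * self.fn(t)

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(getattr(self.fn, "breakpoints", ()))


def _collect_breakpoints(params: ModelParams, t_end: float, extra) -> list[float]:
    pts = set()
    if params.therapy_fn is not None:
        pts.update(getattr(params.therapy_fn, "breakpoints", ()))
    if extra is not None:
        pts.update(extra)
    return sorted(p for p in pts if 0.0 < p < t_end)


def simulate(
    params: ModelParams,
    init: CloneState | Sequence[float],
    t_end: float,
    sample_days: Sequence[float] | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    absorbing_floor: float | None = None,
    breakpoints: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the model and sample it on a day grid.

    ``sample_days`` defaults to daily samples 0..t_end (the cadence of the
    culture measurements).  ``breakpoints`` marks times where the right-hand
    side is non-smooth (dose administrations); the integration restarts
    there.  Therapy functions exposing a ``breakpoints`` attribute are
    handled automatically.  With ``absorbing_floor`` set, a clone crossing
    the floor from above is zeroed and pinned for the remainder.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    init = CloneState.coerce(init)
    if sample_days is None:
        sample_days = np.arange(0.0, np.floor(t_end) + 1.0)
        if sample_days[-1] < t_end:
            sample_days = np.append(sample_days, t_end)
    samples = np.asarray(sample_days, dtype=float)
    if samples.ndim != 1 or len(samples) == 0 or np.any(np.diff(samples) <= 0):
        raise ValueError("sample_days must be a nonempty strictly increasing grid")
    if samples[0] < 0 or samples[-1] > t_end:
        raise ValueError("sample_days must lie within [0, t_end]")

    base_rhs = rhs_function(params)
    pinned = init.as_array() <= 0.0  # an absent clone never appears

    def rhs(t, y):
        d = base_rhs(t, y)
        if pinned[0]:
            d[0] = 0.0
        if pinned[1]:
            d[1] = 0.0
        return d

    segment_edges = _collect_breakpoints(params, t_end, breakpoints) + [float(t_end)]

    events = None
    if absorbing_floor is not None:

        def hit_floor_g(t, y):
            return y[0] - absorbing_floor

        def hit_floor_r(t, y):
            return y[1] - absorbing_floor

        for ev in (hit_floor_g, hit_floor_r):
            ev.terminal = True
            ev.direction = -1
        events = [hit_floor_g, hit_floor_r]

    out = np.empty((len(samples), 2), dtype=float)
    filled = np.zeros(len(samples), dtype=bool)
    y = init.as_array()
    t0 = 0.0
    if samples[0] == 0.0:
        out[0] = y
        filled[0] = True

    for t1 in segment_edges:
        while t0 < t1:
            mask = (samples > t0) & (samples <= t1) & ~filled
            t_eval = samples[mask]
            try:
                sol = solve_ivp(
                    rhs,
                    (t0, t1),
                    y,
                    method="LSODA",
                    rtol=rtol,
                    atol=atol,
                    t_eval=t_eval if len(t_eval) else None,
                    events=events,
                    dense_output=True,
                )
            except ValueError as exc:
                # non-finite derivatives break the solver internally
                raise SimulationBlowUp(t0, f"integration failed after t = {t0:g}: {exc}")
            if sol.status == -1 or not np.all(np.isfinite(sol.y)):
                raise SimulationBlowUp(sol.t[-1] if len(sol.t) else t0)
            if sol.status == 1:
                t_stop = min(
                    ev[0] for ev in sol.t_events if len(ev)
                )
            else:
                t_stop = t1
            reached = (samples > t0) & (samples <= t_stop) & ~filled
            if reached.any():
                out[reached] = np.maximum(sol.sol(samples[reached]).T, 0.0)
                filled[reached] = True
            y = np.maximum(sol.sol(t_stop), 0.0)
            if sol.status == 1:  # a clone hit the extinction floor
                for i in (0, 1):
                    if len(sol.t_events[i]) and not pinned[i]:
                        pinned[i] = True
                        y[i] = 0.0
            t0 = t_stop
    # clamp sampled states that landed on a pinned clone after its event
    if not np.all(filled):  # pragma: no cover - defensive
        raise RuntimeError("integration ended before covering the sample grid")
    if not np.all(np.isfinite(out)):
        raise SimulationBlowUp(float(samples[np.argmax(~np.isfinite(out).all(axis=1))]))
    return Trajectory(times=samples, states=out, params=params)


def steady_state(
    params: ModelParams,
    init: CloneState | Sequence[float],
    t_max: float = 1000.0,
    tol: float = 1e-6,
    *,
    chunk: float = 25.0,
    **sim_kwargs,
) -> SteadyStateResult:
    """Integrate until per-capita rates fall below ``tol`` (day^-1).

    Convergence is declared when ``|dX/dt| / max(X, 1) < tol`` for both
    clones -- scale-free, so it is equally strict for 1e5-cell cultures and
    1e12-cell tumors.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    init = CloneState.coerce(init)
    state = init
    t = 0.0
    while t < t_max:
        step = min(chunk, t_max - t)
        traj = simulate(params, state, step, sample_days=[0.0, step], **sim_kwargs)
        state = traj.final_state()
        t += step
        dg, dr = full_rhs(t, state, params)
        rate = max(
            abs(dg) / max(state.sensitive, 1.0),
            abs(dr) / max(state.resistant, 1.0),
        )
        if rate < tol:
            return SteadyStateResult(state=state, converged=True, t_reached=t)
    return SteadyStateResult(state=state, converged=False, t_reached=None)


def phase_portrait(
    params: ModelParams,
    total_init: float,
    fractions: Sequence[float],
    t_mark: float = 5.0,
    t_end: float = 100.0,
    **sim_kwargs,
) -> PhasePortrait:
    """One trajectory per initial resistant fraction at a fixed total seed.

    States at ``t_mark`` (the day-5 culture endpoint) and at ``t_end`` are
    recorded separately, mirroring the short-term vs long-term markers on
    the portraits.
    """
    if total_init <= 0:
        raise ValueError("total_init must be > 0")
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    trajectories = []
    for f in fractions:
        init = CloneState(total_init * (1.0 - f), total_init * f)
        sample = np.unique(
            np.concatenate([np.arange(0.0, t_end + 1.0), [t_mark, t_end]])
        )
        sample = sample[sample <= t_end]
        trajectories.append(simulate(params, init, t_end, sample, **sim_kwargs))

    def at(traj: Trajectory, t: float) -> np.ndarray:
        return traj.states[np.searchsorted(traj.times, t)]

    marks_mid = np.array([at(tr, t_mark) for tr in trajectories])
    marks_end = np.array([tr.states[-1] for tr in trajectories])
    return PhasePortrait(fractions, trajectories, marks_mid, marks_end)


def gr_ratio_series(traj: Trajectory) -> np.ndarray:
    """Sensitive/resistant count ratio per sample day; NaN where R = 0."""
    g, r = traj.sensitive, traj.resistant
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r > 0, g / r, np.nan)


def concentration_sweep(
    params: ModelParams,
    grid: Sequence[float],
    init: CloneState | Sequence[float],
    t_end: float,
    *,
    extinction_floor: float = EXTINCTION_FLOOR,
    materiality: float = 0.05,
    **sim_kwargs,
) -> SweepResult:
    """End states across a grid of therapy-concentration multipliers.

    Each run scales the model's concentration function by one grid value.
    The shift classification operationalizes the visual distinction between
    the two steady-state regimes: *abrupt* if the terminal sensitive count
    drops from above ``materiality`` (as a share of the terminal total)
    straight to extinction between adjacent grid points, *gradual* if it
    declines below that share before extinguishing, *none* if it never
    extinguishes on the grid.
    """
    if params.therapy is None or params.therapy_fn is None:
        raise ValueError("concentration_sweep requires a model with therapy")
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")

    end_states = np.empty((len(grid), 2), dtype=float)
    for i, c in enumerate(grid):
        scaled = replace(params, therapy_fn=ScaledTherapy(params.therapy_fn, c))
        traj = simulate(
            scaled, init, t_end, sample_days=[0.0, t_end],
            absorbing_floor=extinction_floor, **sim_kwargs,
        )
        end = traj.states[-1].copy()
        end[end < extinction_floor] = 0.0
        end_states[i] = end

    g_end = end_states[:, 0]
    extinct = np.flatnonzero(g_end == 0.0)
    if len(extinct) == 0:
        shift, threshold = "none", None
    else:
        j = int(extinct[0])
        threshold = float(grid[j])
        if j == 0:
            shift = "gradual"  # extinct already at the lowest concentration
        else:
            share = g_end[j - 1] / max(end_states[j - 1].sum(), 1.0)
            shift = "abrupt" if share > materiality else "gradual"
    return SweepResult(grid, end_states, shift, threshold)


def sweep_to_frame(result: SweepResult) -> pd.DataFrame:
    """Tabular form: concentration, end counts and the shift flag."""
    return pd.DataFrame(
        {
            "concentration": result.concentrations,
            "end_sensitive": result.end_states[:, 0],
            "end_resistant": result.end_states[:, 1],
            "shift_flag": result.shift_type,
        }
    )
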