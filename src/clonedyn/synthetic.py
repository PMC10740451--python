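"""In-silico stand-in for the fluorescence coculture experiments.

Generates daily per-clone counts for pure and mixed cultures from a chosen
ground-truth model plus multiplicative lognormal measurement noise, so the
rate-inference and calibration machinery can be exercised end to end
without any laboratory data.  Defaults mirror the culture design: 100,000
total cells seeded at sensitive:resistant ratios 1:0, 3:1, 1:1, 1:3 and
0:1, counted daily through day 5, saturating near 600,000 cells, with
pure-culture rates of about 1.069 day^-1 (sensitive) and 0.4695 day^-1
(resistant).

The noise model is lognormal per count (imaging-cytometry error is roughly
proportional to the count) with a default CV of 5%; counts are rounded to
whole cells and a clone seeded at zero stays at zero.  Clumping of the two
cell types, media additions mid-culture, transduction efficiency and
sorting purity are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CloneState, GrowthParams, InteractionParams, ModelParams, params_to_dict
from .rates import RateProfile, REFERENCE_ANCHORS, calibrate_to_anchor_rates
from .simulate import simulate

__all__ = [
    "CultureDesign",
    "CultureDataset",
    "generate_cultures",
    "reference_invitro_profile",
    "default_truth_params",
]


@dataclass(frozen=True)
class CultureDesign:
    """Factorial layout of the emulated culture experiment."""

    total_init: float = 1e5
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_init <= 0:
            raise ValueError("total_init must be > 0")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class CultureDataset:
    """Long-format counts plus the generating model parameters."""

    data: pd.DataFrame  # fraction_resistant, replicate, day, sensitive_count, resistant_count
    truth: ModelParams
    design: CultureDesign

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def truth_config(self) -> dict:
        return params_to_dict(self.truth)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with the requested coefficient of variation."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_cultures(truth: ModelParams, design: CultureDesign) -> CultureDataset:
    """Simulate the design and overlay measurement noise.

    Deterministic given ``design.seed``.  Each fraction is integrated once;
    replicates differ only in their noise draws.  Zero counts stay zero (an
    absent clone cannot appear through measurement error).
    """
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.days, dtype=float)
    rows = []
    for frac in design.fractions:
        init = CloneState(
            design.total_init * (1.0 - frac), design.total_init * frac
        )
        traj = simulate(truth, init, t_end=days[-1], sample_days=days)
        clean = traj.states  # (n_days, 2)
        for rep in range(design.replicates):
            noise = _lognormal_factor(rng, design.noise_cv, clean.shape)
            noisy = np.rint(clean * noise)
            noisy[clean == 0.0] = 0.0
            for d, (g, r) in zip(days, noisy):
                rows.append((frac, rep, d, g, r))
    df = pd.DataFrame(
        rows,
        columns=[
            "fraction_resistant",
            "replicate",
            "day",
            "sensitive_count",
            "resistant_count",
        ],
    )
    return CultureDataset(data=df, truth=truth, design=design)


def reference_invitro_profile() -> RateProfile:
    """The four printed anchor rates, packaged as an observed profile.

    Pure-culture rates at resistant fractions 0 and 1 plus the 1:1 mixture
    maxima; the cells never printed (a clone's rate in the culture where it
    is absent, and the off-anchor mixtures) are NaN.
    """
    fractions = np.array([0.0, 0.5, 1.0])
    k_s = np.array(
        [
            REFERENCE_ANCHORS[("sensitive", 0.0)],
            REFERENCE_ANCHORS[("sensitive", 0.5)],
            np.nan,
        ]
    )
    k_r = np.array(
        [
            np.nan,
            REFERENCE_ANCHORS[("resistant", 0.5)],
            REFERENCE_ANCHORS[("resistant", 1.0)],
        ]
    )
    return RateProfile(fractions, k_s, k_r)


def default_truth_params(m: float = 2.0) -> ModelParams:
    """Ground truth for the generator: anchor-calibrated mutualism.

    Pure rates at the printed monoculture values, capacity 600,000 cells,
    and weighted mutualistic constants fitted to the printed 1:1 mixture
    rate maxima for the given exponent.
    """
    c_gr, c_rg = calibrate_to_anchor_rates(m)
    return ModelParams(
        GrowthParams(
            REFERENCE_ANCHORS[("sensitive", 0.0)],
            REFERENCE_ANCHORS[("resistant", 1.0)],
            6e5,
        ),
        InteractionParams(c_gr, c_rg, m=m, weighted=True),
    )
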