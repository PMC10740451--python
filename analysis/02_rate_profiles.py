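#!/usr/bin/env python
"""Short-horizon rate-constant profiles across initial mixtures.

For each initial resistant fraction, the mixed culture is simulated for
five days and each clone's daily counts are fitted with the standard
logistic; the fitted rate constants form the "interpolated" profile that
distinguishes interaction structures on experimental timescales.

Finding: without interaction the sensitive clone's rate falls almost
linearly as the resistant fraction rises; with anchor-calibrated mutualism
(m = 2) it rises at small resistant fractions and falls at large ones --
the non-monotone fingerprint also seen in the fluorescence cultures.
"""

import argparse
from pathlib import Path

import numpy as np

from clonedyn import ModelParams, interpolated_rate_profile
from clonedyn.experiments import INVITRO_GROWTH
from clonedyn.model import InteractionParams
from clonedyn.rates import calibrate_to_anchor_rates


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    fractions = np.round(np.linspace(0.0, 1.0, 11), 10)

    plain = interpolated_rate_profile(ModelParams(INVITRO_GROWTH), fractions=fractions)
    plain.to_csv(args.out_dir / "rate_profile_noninteracting.csv")

    c_gr, c_rg = calibrate_to_anchor_rates(2.0)
    mut = interpolated_rate_profile(
        ModelParams(
            INVITRO_GROWTH, InteractionParams(c_gr, c_rg, m=2.0, weighted=True)
        ),
        fractions=fractions,
    )
    mut.to_csv(args.out_dir / "rate_profile_mutualistic_m2.csv")

    print(f"wrote rate profiles to {args.out_dir}")
    ks = plain.k_sensitive[:-1]
    print(f"  non-interacting k_sensitive: {ks[0]:.3f} -> {ks[-1]:.3f} "
          f"(monotone decline: {bool(np.all(np.diff(ks) < 0))})")
    km = mut.k_sensitive[:-1]
    peak = np.nanargmax(km)
    print(f"  mutualistic (m=2, C=({c_gr:.3f},{c_rg:.3f})) k_sensitive peaks at "
          f"resistant fraction {fractions[peak]:.1f}: {km[peak]:.3f} day^-1")


if __name__ == "__main__":
    main()
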