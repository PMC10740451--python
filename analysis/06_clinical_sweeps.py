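#!/usr/bin/env python
"""Clinical-scale dosing sweeps: does mutualism shelter resistant cells?

Scales the culture-calibrated models to tumor scale (10^9 cells at
diagnosis, 9:1 sensitive:resistant, capacity 2^40 cells; sensitive growth
from the 29-day or 14-day doubling time), applies the obinutuzumab
schedule (1000 mg on days 0/7/14, then each 21-day cycle start through day
147; half-life 28.4 days) times a concentration multiplier, and records
day-1500 populations.

Finding: without interaction the resistant compartment peaks in a narrow
multiplier window just past the sensitive clone's extinction; with
mutualistic interaction resistant cells persist in force down to zero
concentration, while high multipliers clear both clones in every scenario.
"""

import argparse
from pathlib import Path

import pandas as pd

from clonedyn.experiments import run_clinical_suite, write_manifest


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    frames = [run_clinical_suite(case) for case in ("slow", "fast")]
    df = pd.concat(frames, ignore_index=True)
    out = args.out_dir / "clinical_sweeps.csv"
    df.to_csv(out, index=False)
    write_manifest(
        args.out_dir / "clinical_manifest.json",
        {"cases": "slow(29d), fast(14d)", "t_end": 1500, "capacity": 2**40},
    )

    print(f"wrote {out}")
    for (case, inter), sub in df.groupby(["growth_case", "interaction"]):
        peak = sub.loc[sub.end_resistant.idxmax()]
        print(
            f"  {case:>4} / {inter:>5}: resistant peak {peak.end_resistant:.3g} "
            f"cells at multiplier {peak.concentration:.3g}"
        )


if __name__ == "__main__":
    main()
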