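#!/usr/bin/env python
"""B1 sensitivity of the MT parameters.

Simulates the MT acquisition with B1 multipliers 0.8-1.2 (scaling both the
achieved readout flips and the MT saturation power) and reports the median
relative error of MTR and of the B1-independent saturation delta; the
latter should stay near zero while MTR drifts roughly as B1^2.
Writes results/b1/b1_sensitivity.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import fibromap as fm


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/b1"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    gt = fm.make_phantom(fm.PhantomSpec(grid_shape=(10, 10, 4), n_regions=3,
                                        seed=args.seed))
    rows = []
    for b1 in (0.8, 0.9, 1.0, 1.1, 1.2):
        maps = fm.mt_maps(fm.simulate_mt(gt, b1=b1), gt.roi)
        row = {"b1": b1}
        for name in ("MTR", "delta", "ka", "T1"):
            truth = gt.maps[name][gt.roi]
            got = maps[name][gt.roi]
            row[f"{name}_err_pct"] = 100 * float(
                np.nanmedian(np.abs(got - truth) / truth))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "b1_sensitivity.csv", index=False)
    print(df.round(3).to_string(index=False))
    print("\ndelta stays within a fraction of a percent while MTR drifts "
          "with the B1 error, mirroring its design as a B1-robust measure.")


if __name__ == "__main__":
    main()
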