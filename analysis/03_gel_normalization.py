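#!/usr/bin/env python
"""Quantify bulk repair from the alkaline-gel lanes (lesion density per
timepoint, percent repaired relative to 0 min) and derive the normalization
factors F_gel(t) that anchor the sequencing-based repair fractions.
"""

import argparse
import json
from pathlib import Path

from photorepair import gel, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/gel"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    lanes = io.read_gel_lanes(args.simdir / "gel_lanes.tsv")
    summary = gel.repair_summary(lanes)
    io.write_table(summary, args.outdir / "repair_summary.tsv")
    factors = {f"{row.timepoint:g}": float(row.fraction_remaining)
               for row in summary.itertuples()}
    (args.outdir / "normalization.json").write_text(json.dumps(factors, indent=2))

    print(summary.to_string(index=False))
    truth = json.loads((args.simdir / "config.json").read_text())
    truth = truth["true_fraction_remaining"]
    for t, f in factors.items():
        print(f"t={t} min: gel-measured fraction remaining {f:.3f} "
              f"(simulation truth {truth[t]:.3f})")
    print(f"normalization factors written to {args.outdir / 'normalization.json'}")


if __name__ == "__main__":
    main()
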