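#!/usr/bin/env python
"""Repair inhibition at TF binding sites: per-TF core (-4..+4) vs flank
(±100) statistics with the >=100-core-CPD filter, the ±500-bp Reb1 site
profile with the <10-CPD mask, and the bound vs low-occupancy control
split (occupancy < 10).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from photorepair import gel, io, tfbs
from photorepair.calling import build_track


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--geldir", type=Path, default=Path("results/gel"))
    ap.add_argument("--outdir", type=Path, default=Path("results/tfbs"))
    ap.add_argument("--timepoint", type=float, default=30.0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = io.read_fasta(args.simdir / "genome.fa")
    t0, _ = build_track(io.read_bed(args.simdir / "reads_t0.bed"), genome)
    tt, _ = build_track(
        io.read_bed(args.simdir / f"reads_t{args.timepoint:g}.bed"), genome
    )
    factors = json.loads((args.geldir / "normalization.json").read_text())
    f_gel = factors[f"{args.timepoint:g}"]
    norm = gel.gel_anchor(t0, tt, f_gel)
    sites = tfbs.load_tfbs(pd.read_csv(args.simdir / "tfbs.tsv", sep="\t"),
                           genome.lengths)

    scatter = tfbs.tf_scatter(t0, tt, sites, norm)
    io.write_table(scatter, args.outdir / "core_flank_scatter.tsv")
    print(f"genome-average fraction remaining (gel anchor): {f_gel:.3f}")
    if scatter.empty:
        print("no TF passed the >=100 core-CPD filter")
    else:
        print(scatter.round(4).to_string(index=False))

    bound, control = tfbs.occupancy_split(sites)
    for name, subset in (("bound (occupancy >= 10)", bound),
                         ("low-occupancy control", control)):
        stat = tfbs.tf_core_flank(t0, tt, subset, norm, min_core_cpds=0)
        if stat is not None:
            print(f"  {name}: f_core={stat.f_core:.3f} f_flank={stat.f_flank:.3f} "
                  f"delta={stat.delta:+.3f} ({stat.n_sites} sites)")

    reb1 = sites[sites["tf"] == "Reb1"]
    prof = tfbs.tf_site_profile(t0, tt, reb1, norm, window=500)
    io.write_table(prof, args.outdir / "reb1_site_profile.tsv")
    print(f"profiles written to {args.outdir}")


if __name__ == "__main__":
    main()
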