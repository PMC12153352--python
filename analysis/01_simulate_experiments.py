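#!/usr/bin/env python
"""Generate the synthetic study: a genome with genes, nucleosome dyads and
Reb1 binding sites; UV damage; a photoreactivated NER-deficient repair time
course (0/30/60 min); CPD-seq-style reads; alkaline-gel lanes; and a UV
passaging mutation table.

Everything downstream (02-07) reads from results/sim/.  Rerunning with the
same seed reproduces every file byte for byte.
"""

import argparse
import json
from pathlib import Path

from photorepair import io, synth

STRAIN = "rad14+PR"
TIMEPOINTS = [0.0, 30.0, 60.0]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    genome = synth.make_genome(args.seed, length=300_000, gc=0.40)
    ann = synth.make_annotations(
        genome, n_genes=60, n_dyads=800,
        tf_specs=[
            {"tf": "Reb1", "n_sites": 120, "occupancy": 50.0},
            {"tf": "Reb1_low", "n_sites": 60, "occupancy": 5.0},
        ],
        seed=args.seed + 1,
    )
    model = synth.RepairRateModel(
        ts_occlusion=0.45,
        nuc_rotational_amp=0.3,
        nuc_rotational_phase=2.0,
        nuc_3prime_attenuation=0.6,
        tfbs_block=0.8,
    )
    damage = synth.simulate_damage(genome, dose_scale=0.5, seed=args.seed + 2)
    exp = synth.simulate_repair(damage, model, ann, TIMEPOINTS, STRAIN, seed=args.seed + 3)

    io.write_fasta(genome, out / "genome.fa")
    ann.write(out)
    for t in TIMEPOINTS:
        reads, skipped = synth.lesions_to_reads(
            exp.surviving_lesions[t], background_nondipy_reads=0.1,
            seed=args.seed + 10 + int(t), name=f"{STRAIN}_{t:g}min",
        )
        io.write_bed(reads, out / f"reads_t{t:g}.bed")
        print(f"t={t:g} min: {exp.surviving_lesions[t].N} lesions -> "
              f"{len(reads)} reads ({skipped} skipped at chromosome ends)")

    phi0 = 0.8  # CPDs/kb immediately after irradiation
    lanes = synth.simulate_gel_lanes(
        {t: phi0 * exp.true_fraction_remaining[t] for t in TIMEPOINTS},
        seed=args.seed + 4,
    )
    io.write_gel_lanes(lanes, out / "gel_lanes.tsv")

    muts = synth.simulate_passaging_mutations(
        ann, genome, n_isolates=20, mean_per_isolate=91,
        ts_fold=8.0, channel_ts_fold={"T>A@NTA": 1.0}, recurrent_fraction=0.02,
        seed=args.seed + 5,
    )
    muts.to_csv(out / "mutations.tsv", sep="\t", index=False)

    config = {
        "seed": args.seed, "strain": STRAIN, "timepoints": TIMEPOINTS,
        "true_fraction_remaining": {f"{t:g}": exp.true_fraction_remaining[t]
                                    for t in TIMEPOINTS},
        "phi0_cpds_per_kb": phi0,
    }
    (out / "config.json").write_text(json.dumps(config, indent=2))
    print(f"true fraction remaining: "
          f"{ {f'{t:g}': round(exp.true_fraction_remaining[t], 4) for t in TIMEPOINTS} }")
    print(f"simulated study written to {out}")


if __name__ == "__main__":
    main()
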