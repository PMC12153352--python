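#!/usr/bin/env python
"""Strand-resolved UV mutation analysis of the passaging isolates: unique-
mutation filtering, the trinucleotide spectrum (C>T in dipyrimidine
contexts; T>A at NTA), the 6-bin gene-body distribution with the TS/NTS
fold, the trinucleotide-normalized transcriptional asymmetry, and the fold
after excluding the photolyase-resistant T>A@NTA class.
"""

import argparse
from pathlib import Path

import pandas as pd

from photorepair import io, mutations as mut


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/mutations"))
    ap.add_argument("--min-asym-count", type=int, default=30)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = io.read_fasta(args.simdir / "genome.fa")
    genes = pd.read_csv(args.simdir / "genes.tsv", sep="\t")
    records = mut.validate_records(
        pd.read_csv(args.simdir / "mutations.tsv", sep="\t"), genome
    )
    unique = mut.unique_filter(records)
    print(f"{len(unique)}/{len(records)} records retained by the unique-mutation "
          f"filter; median {records.groupby('isolate').size().median():.0f} "
          f"mutations per isolate")

    spectrum = mut.trinuc_spectrum(unique, genome, genes)
    io.write_table(spectrum, args.outdir / "trinuc_spectrum.tsv")
    ct_dipy = spectrum[(spectrum.mut_class == "C>T") & spectrum.dipy]["count"].sum()
    ta_nta = spectrum[(spectrum.mut_class == "T>A")
                      & (spectrum.context.str[2] == "A")]["count"].sum()
    print(f"spectrum: C>T in dipyrimidine contexts = {100 * ct_dipy / len(unique):.1f}%, "
          f"T>A at NTA = {100 * ta_nta / len(unique):.1f}% of unique mutations")

    dist = mut.gene_body_distribution(unique, genes, genome)
    io.write_table(dist, args.outdir / "gene_body_distribution.tsv")
    fold = mut.ts_nts_fold(dist)
    no_nta = mut.exclude_class(unique, "T>A@NTA", genome)
    fold_no_nta = mut.ts_nts_fold(mut.gene_body_distribution(no_nta, genes, genome))
    print(f"gene-body TS:NTS mutation fold = {fold:.2f}; "
          f"excluding T>A@NTA = {fold_no_nta:.2f}")

    asym = mut.transcriptional_asymmetry(unique, genes, genome, args.min_asym_count)
    io.write_table(asym, args.outdir / "transcriptional_asymmetry.tsv")
    solid = asym[~asym.flagged & asym.A.notna()]
    print(f"{len(solid)} channels with >= {args.min_asym_count} mutations; "
          f"normalized TS/NTS ratios span "
          f"{solid.A.min():.2f}-{solid.A.max():.2f}")
    print(f"tables written to {args.outdir}")


if __name__ == "__main__":
    main()
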