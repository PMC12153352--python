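"""Annotation containers: genes (TSS/TES/strand/transcription rate),
nucleosome dyads (position/score) and TF binding sites (midpoint/strand/
occupancy), with TSV readers and writers.

Gene coordinates are 1-based; ``tss``/``tes`` are oriented (tss > tes for
minus-strand genes is *not* used — instead ``strand`` carries orientation
and tss < tes always denotes the genomic span only when strand is '+';
for '-' genes the TSS is the rightmost coordinate, so tss > tes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GENE_COLUMNS = ["chrom", "tss", "tes", "strand", "rate_mrna_per_h"]
DYAD_COLUMNS = ["chrom", "pos", "score"]
TFBS_COLUMNS = ["tf", "chrom", "midpoint", "strand", "occupancy"]


@dataclass
class AnnotationSet:
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    dyads: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DYAD_COLUMNS))
    tfbs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TFBS_COLUMNS))

    def validate(self, genome=None) -> None:
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise ValueError(f"genes table missing column {col!r}")
        for col in DYAD_COLUMNS:
            if col not in self.dyads.columns:
                raise ValueError(f"dyads table missing column {col!r}")
        for col in TFBS_COLUMNS[:4]:
            if col not in self.tfbs.columns:
                raise ValueError(f"tfbs table missing column {col!r}")
        if genome is not None:
            for table, poscols in (
                (self.genes, ("tss", "tes")),
                (self.dyads, ("pos",)),
                (self.tfbs, ("midpoint",)),
            ):
                for _, row in table.iterrows():
                    if row["chrom"] not in genome:
                        raise ValueError(f"unknown chromosome {row['chrom']!r}")
                    L = genome.lengths[row["chrom"]]
                    for c in poscols:
                        if not (1 <= row[c] <= L):
                            raise ValueError(
                                f"position {row[c]} ({c}) outside {row['chrom']} (len {L})"
                            )

    # -- I/O ---------------------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in (("genes", self.genes), ("dyads", self.dyads), ("tfbs", self.tfbs)):
            p = outdir / f"{prefix}{name}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths

    @classmethod
    def read(cls, genes=None, dyads=None, tfbs=None) -> "AnnotationSet":
        kwargs = {}
        if genes is not None:
            kwargs["genes"] = pd.read_csv(genes, sep="\t")
        if dyads is not None:
            kwargs["dyads"] = pd.read_csv(dyads, sep="\t")
        if tfbs is not None:
            kwargs["tfbs"] = pd.read_csv(tfbs, sep="\t")
        return cls(**kwargs)


def gene_body(row) -> tuple[int, int]:
    """Genomic (leftmost, rightmost) 1-based span of a gene row."""
    lo, hi = sorted((int(row["tss"]), int(row["tes"])))
    return lo, hi


def template_strand(gene_strand: str) -> str:
    """The transcribed (template) strand is the strand opposite the gene's
    annotated mRNA-sense strand."""
    if gene_strand == "+":
        return "-"
    if gene_strand == "-":
        return "+"
    raise ValueError(f"bad gene strand {gene_strand!r}")
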