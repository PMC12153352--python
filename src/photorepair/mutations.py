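"""Strand-resolved analysis of UV passaging mutations.

All single-base substitutions are standardized to the pyrimidine frame:
records whose reference base is a purine are reverse-complemented (exactly
once) so every mutation is one of the six classes C>A, C>G, C>T, T>A, T>C,
T>G in a 16-context trinucleotide frame (5' base + ref + 3' base, read on
the strand carrying the pyrimidine).  Within gene bodies a mutation is
assigned to the transcribed strand (TS) when its pyrimidine-frame reference
lies on the template strand, mirroring the lesion-on-template logic of the
repair analysis.  Transcriptional asymmetry normalizes the per-strand
mutation counts by the per-strand trinucleotide content of gene bodies:

    A = (m_TS / k_TS) / (m_NTS / k_NTS)
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .annotations import gene_body, template_strand
from .genome import Genome, revcomp
from .genes import CODING_BINS, FLANK_BINS, FLANK_WIDTH, gene_bins

logger = logging.getLogger(__name__)

PY_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def contexts_for(ref: str) -> list[str]:
    """The 16 trinucleotide contexts with the given pyrimidine reference."""
    return [a + ref + b for a, b in itertools.product("ACGT", "ACGT")]


def is_dipyrimidine_context(context: str) -> bool:
    """True when the central pyrimidine has a 5' or 3' pyrimidine neighbor
    (the lesion-forming configuration)."""
    return context[0] in "CT" or context[2] in "CT"


def validate_records(records: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Drop non-SNV rows (logged) and raise on reference mismatches."""
    recs = records.copy()
    snv = recs["ref"].str.len().eq(1) & recs["alt"].str.len().eq(1)
    snv &= recs["ref"].isin(list("ACGT")) & recs["alt"].isin(list("ACGT"))
    if (~snv).any():
        logger.info("skipping %d non-SNV records", int((~snv).sum()))
        recs = recs[snv]
    bad = []
    for i, row in recs.iterrows():
        if genome.seq(row["chrom"], row["pos"], row["pos"]) != row["ref"]:
            bad.append((row["chrom"], int(row["pos"]), row["ref"]))
    if bad:
        raise ValueError(f"reference mismatches at {bad[:10]}{'...' if len(bad) > 10 else ''}")
    return recs.reset_index(drop=True)


def unique_filter(records: pd.DataFrame, keep_one: bool = False) -> pd.DataFrame:
    """Retain only unique mutations.

    A substitution (chrom, pos, ref, alt) observed in two or more isolates is
    treated as recurrent (likely ancestral) and every copy is removed; with
    ``keep_one=True`` a single representative is retained instead.
    """
    key = ["chrom", "pos", "ref", "alt"]
    n_isolates = records.groupby(key)["isolate"].transform("nunique")
    if keep_one:
        recurrent = n_isolates >= 2
        dedup = records[recurrent].drop_duplicates(subset=key)
        return (
            pd.concat([records[~recurrent], dedup]).sort_index().reset_index(drop=True)
        )
    return records[n_isolates < 2].reset_index(drop=True)


def pyrimidine_frame(records: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Annotate records with pyrimidine-frame class, context and strand.

    Adds columns ``py_strand`` ('+' when the reference pyrimidine is on the
    plus strand), ``mut_class`` (e.g. 'C>T'), ``context`` (py-frame
    trinucleotide) and ``dipy`` (lesion-forming context flag).  Records at a
    chromosome end (no flanking base) are excluded with a log message.
    """
    recs = records.copy()
    L = recs["chrom"].map(genome.lengths)
    at_end = (recs["pos"] <= 1) | (recs["pos"] >= L)
    if at_end.any():
        logger.info("excluding %d records at chromosome ends", int(at_end.sum()))
        recs = recs[~at_end]
    py_strand, mut_class, context = [], [], []
    for _, row in recs.iterrows():
        tri = genome.seq(row["chrom"], row["pos"] - 1, row["pos"] + 1)
        if row["ref"] in "CT":
            py_strand.append("+")
            mut_class.append(f"{row['ref']}>{row['alt']}")
            context.append(tri)
        else:
            py_strand.append("-")
            mut_class.append(f"{_COMP[row['ref']]}>{_COMP[row['alt']]}")
            context.append(revcomp(tri))
    recs["py_strand"] = py_strand
    recs["mut_class"] = mut_class
    recs["context"] = context
    recs["dipy"] = [is_dipyrimidine_context(c) for c in recs["context"]]
    return recs.reset_index(drop=True)


def trinuc_spectrum(
    records: pd.DataFrame, genome: Genome, genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Strand-resolved trinucleotide mutation spectrum.

    Returns one row per (class, context) channel with ``count`` and the
    dipyrimidine-context flag; with ``genes`` given, additional ``count_TS``
    and ``count_NTS`` columns count gene-body mutations by transcribed-strand
    assignment.  The channel counts sum to the number of contributing
    records.
    """
    annotated = pyrimidine_frame(records, genome)
    channels = [
        (cls, ctx) for cls in PY_CLASSES for ctx in contexts_for(cls[0])
    ]
    counts = annotated.groupby(["mut_class", "context"]).size()
    rows = []
    strand_counts = None
    if genes is not None:
        assigned = assign_mutation_strand(annotated, genes)
        in_gene = assigned[assigned["strand_class"].isin(["TS", "NTS"])]
        strand_counts = in_gene.groupby(["mut_class", "context", "strand_class"]).size()
    for cls, ctx in channels:
        row = {
            "mut_class": cls,
            "context": ctx,
            "count": int(counts.get((cls, ctx), 0)),
            "dipy": is_dipyrimidine_context(ctx),
        }
        if strand_counts is not None:
            row["count_TS"] = int(strand_counts.get((cls, ctx, "TS"), 0))
            row["count_NTS"] = int(strand_counts.get((cls, ctx, "NTS"), 0))
        rows.append(row)
    return pd.DataFrame(rows)


def assign_mutation_strand(annotated: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Add ``strand_class`` (TS/NTS/intergenic) per record.

    A mutation inside a gene body is TS when its pyrimidine-frame reference
    lies on the template strand.  A record inside several overlapping genes
    follows the first gene in table order (the synthetic generator never
    overlaps genes).
    """
    out = annotated.copy()
    out["strand_class"] = "intergenic"
    for _, gene in genes.iterrows():
        lo, hi = gene_body(gene)
        in_body = (
            (out["chrom"] == gene["chrom"])
            & (out["pos"] >= lo)
            & (out["pos"] <= hi)
            & (out["strand_class"] == "intergenic")
        )
        ts = template_strand(gene["strand"])
        out.loc[in_body, "strand_class"] = np.where(
            out.loc[in_body, "py_strand"] == ts, "TS", "NTS"
        )
    return out


def gene_body_distribution(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    genome: Genome,
    n_bins: int = CODING_BINS,
    flank_bins: int = FLANK_BINS,
    flank_width: int = FLANK_WIDTH,
) -> pd.DataFrame:
    """Mutation counts per gene bin (6 coding + 3x167-bp flanks) and strand.

    Binning is identical to the repair gene profiles; a mutation in
    overlapping genes is counted once per gene it falls in.
    """
    annotated = pyrimidine_frame(records, genome)
    labels = (
        [f"up{i}" for i in range(flank_bins, 0, -1)]
        + [f"b{i}" for i in range(1, n_bins + 1)]
        + [f"dn{i}" for i in range(1, flank_bins + 1)]
    )
    counts = {(lbl, sc): 0 for lbl in labels for sc in ("TS", "NTS")}
    for _, gene in genes.iterrows():
        try:
            bins = gene_bins(
                int(gene["tss"]), int(gene["tes"]), gene["strand"],
                n_bins=n_bins, flank_bins=flank_bins, flank_width=flank_width,
            )
        except ValueError:
            continue
        on_chrom = annotated[annotated["chrom"] == gene["chrom"]]
        ts = template_strand(gene["strand"])
        for lbl, a, b in bins:
            hits = on_chrom[(on_chrom["pos"] >= a) & (on_chrom["pos"] <= b)]
            counts[(lbl, "TS")] += int((hits["py_strand"] == ts).sum())
            counts[(lbl, "NTS")] += int((hits["py_strand"] != ts).sum())
    rows = [
        {"bin": lbl, "strand_class": sc, "count": counts[(lbl, sc)]}
        for lbl in labels
        for sc in ("TS", "NTS")
    ]
    return pd.DataFrame(rows)


def ts_nts_fold(distribution: pd.DataFrame, coding_only: bool = True) -> float:
    """Aggregate TS:NTS mutation-count ratio from a gene-body distribution."""
    d = distribution
    if coding_only:
        d = d[d["bin"].str.startswith("b")]
    ts = d.loc[d["strand_class"] == "TS", "count"].sum()
    nts = d.loc[d["strand_class"] == "NTS", "count"].sum()
    if nts == 0:
        return float("inf")
    return float(ts / nts)


def context_occurrences_by_strand(genome: Genome, genes: pd.DataFrame) -> pd.DataFrame:
    """Trinucleotide context occurrences per strand class within gene bodies.

    For every gene-body position whose base (or complement) is a pyrimidine,
    the py-frame context is counted toward TS when the pyrimidine lies on
    the template strand, else NTS.  Returns rows (context, k_TS, k_NTS).
    """
    all_ctx = sorted({c for ref in "CT" for c in contexts_for(ref)})
    k = {(ctx, sc): 0 for ctx in all_ctx for sc in ("TS", "NTS")}
    for _, gene in genes.iterrows():
        lo, hi = gene_body(gene)
        chrom = gene["chrom"]
        L = genome.lengths[chrom]
        lo, hi = max(lo, 2), min(hi, L - 1)
        seq = genome.seq(chrom, lo - 1, hi + 1)  # with 1-base flanks
        ts = template_strand(gene["strand"])
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if tri[1] in "CT":
                sc = "TS" if ts == "+" else "NTS"
                k[(tri, sc)] += 1
            elif tri[1] in "AG":
                sc = "TS" if ts == "-" else "NTS"
                k[(revcomp(tri), sc)] += 1
    return pd.DataFrame(
        [{"context": c, "k_TS": k[(c, "TS")], "k_NTS": k[(c, "NTS")]} for c in all_ctx]
    )


def transcriptional_asymmetry(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    genome: Genome,
    min_count: int = 30,
) -> pd.DataFrame:
    """Trinucleotide-normalized TS/NTS mutation asymmetry per channel.

    A = (m_TS/k_TS) / (m_NTS/k_NTS), with k the per-strand context content of
    gene bodies.  Channels with fewer than ``min_count`` total gene-body
    mutations are reported but flagged; m_NTS = 0 with m_TS > 0 yields +inf.
    """
    annotated = assign_mutation_strand(pyrimidine_frame(records, genome), genes)
    in_gene = annotated[annotated["strand_class"].isin(["TS", "NTS"])]
    m = in_gene.groupby(["mut_class", "context", "strand_class"]).size()
    k = context_occurrences_by_strand(genome, genes).set_index("context")
    rows = []
    for cls in PY_CLASSES:
        for ctx in contexts_for(cls[0]):
            m_ts = int(m.get((cls, ctx, "TS"), 0))
            m_nts = int(m.get((cls, ctx, "NTS"), 0))
            k_ts = int(k.loc[ctx, "k_TS"])
            k_nts = int(k.loc[ctx, "k_NTS"])
            if m_ts == 0 and m_nts == 0:
                a = np.nan
            elif m_nts == 0 or k_ts == 0:
                a = np.inf
            else:
                a = (m_ts / k_ts) / (m_nts / k_nts)
            rows.append(
                {
                    "mut_class": cls,
                    "context": ctx,
                    "m_TS": m_ts,
                    "m_NTS": m_nts,
                    "k_TS": k_ts,
                    "k_NTS": k_nts,
                    "A": a,
                    "dipy": is_dipyrimidine_context(ctx),
                    "flagged": (m_ts + m_nts) < min_count,
                }
            )
    return pd.DataFrame(rows)


def exclude_class(records: pd.DataFrame, class_spec: str | None, genome: Genome) -> pd.DataFrame:
    """Remove records matching a pyrimidine-frame class spec.

    Spec format ``REF>ALT`` optionally ``@ctx`` where ctx is ``dipy`` or a
    3-letter pattern with N wildcards (``NTA`` matches ATA/CTA/GTA/TTA).
    An empty/None spec is the identity.
    """
    if not class_spec:
        return records.reset_index(drop=True)
    if "@" in class_spec:
        cls, ctx = class_spec.split("@", 1)
    else:
        cls, ctx = class_spec, None
    if cls not in PY_CLASSES:
        raise ValueError(f"malformed class spec {class_spec!r}: class must be one of {PY_CLASSES}")
    annotated = pyrimidine_frame(records, genome)
    match = annotated["mut_class"] == cls
    if ctx is not None:
        if ctx == "dipy":
            match &= annotated["dipy"]
        else:
            if len(ctx) != 3 or ctx[1] != cls[0]:
                raise ValueError(
                    f"malformed context {ctx!r}: need 3 bases centred on {cls[0]}"
                )
            for i in (0, 2):
                if ctx[i] != "N":
                    match &= annotated["context"].str[i] == ctx[i]
    kept = annotated[~match]
    return kept[list(records.columns)].reset_index(drop=True)


def canr_frequency(
    colonies_can: int, dilution_can: float, colonies_sc: int, dilution_sc: float
) -> float:
    """Canavanine-resistance mutant frequency from colony counts.

    ``dilution`` is the fold-dilution of the culture plated on each medium,
    so the estimated cell number on a plate is colonies x dilution and

        frequency = (colonies_can * dilution_can) / (colonies_sc * dilution_sc)

    e.g. 25 Can^R colonies from undiluted culture against 50 colonies on SC
    at a 10^4-fold dilution gives 25 / (50 x 10^4) = 5e-5.
    """
    if colonies_sc <= 0:
        raise ValueError("SC plate must have > 0 colonies")
    if dilution_can <= 0 or dilution_sc <= 0:
        raise ValueError("dilution factors must be > 0")
    return (colonies_can * dilution_can) / (colonies_sc * dilution_sc)


def fold_induction(freq_uv: float, freq_control: float) -> float:
    """Mutation-frequency fold induction of the UV-treated condition."""
    if freq_control <= 0:
        raise ValueError("control frequency must be > 0")
    return freq_uv / freq_control
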