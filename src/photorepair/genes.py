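"""Transcribed-strand vs non-transcribed-strand repair profiles over genes.

Each gene's coding span (TSS..TES) is divided into six equal bins oriented
TSS->TES; three fixed 167-bp bins flank the TSS upstream and the TES
downstream.  The transcribed strand (TS, the template) is the strand
opposite the gene's annotated mRNA-sense strand; the NTS is the sense
strand; flank positions inherit the gene's frame.  Per-bin fractions are
computed by summing counts across all genes and then applying the
gel-anchored normalizer (aggregation before division).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import template_strand
from .gel import Normalizer
from .tracks import LesionTrack

logger = logging.getLogger(__name__)

CODING_BINS = 6
FLANK_BINS = 3
FLANK_WIDTH = 167

# bin labels in 5'->3' gene order: farthest-upstream flank first
BIN_ORDER = (
    [f"up{i}" for i in range(FLANK_BINS, 0, -1)]
    + [f"b{i}" for i in range(1, CODING_BINS + 1)]
    + [f"dn{i}" for i in range(1, FLANK_BINS + 1)]
)


def assign_ts_nts(gene_strand: str, lesion_strand: str) -> str:
    """TS if the lesion lies on the template strand, else NTS."""
    return "TS" if lesion_strand == template_strand(gene_strand) else "NTS"


def gene_bins(
    tss: int,
    tes: int,
    strand: str,
    n_bins: int = CODING_BINS,
    flank_bins: int = FLANK_BINS,
    flank_width: int = FLANK_WIDTH,
) -> list[tuple[str, int, int]]:
    """Genomic 1-based inclusive [start, end] spans for every bin of a gene,
    labelled in 5'->3' gene order (up3..up1, b1..b6, dn1..dn3).

    Coding-bin boundaries come from rounding cumulative edges, so the bins
    are deterministic and any remainder bases land in the last bin.
    """
    lo, hi = sorted((tss, tes))
    length = hi - lo + 1
    if length < n_bins:
        raise ValueError(f"gene shorter than {n_bins} bp cannot be binned")
    edges = [round(i * length / n_bins) for i in range(n_bins + 1)]
    out = []
    for label_i, (a, b) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        # oriented offsets a..b-1 from the TSS
        if strand == "+":
            out.append((f"b{label_i}", tss + a, tss + b - 1))
        else:
            out.append((f"b{label_i}", tss - b + 1, tss - a))
    for i in range(1, flank_bins + 1):
        # up{i}: i-th flank bin counting away from the TSS
        if strand == "+":
            out.append((f"up{i}", tss - i * flank_width, tss - (i - 1) * flank_width - 1))
            out.append((f"dn{i}", tes + (i - 1) * flank_width + 1, tes + i * flank_width))
        else:
            out.append((f"up{i}", tss + (i - 1) * flank_width + 1, tss + i * flank_width))
            out.append((f"dn{i}", tes - i * flank_width, tes - (i - 1) * flank_width - 1))
    order = {lbl: i for i, lbl in enumerate(BIN_ORDER)}
    out.sort(key=lambda r: order[r[0]])
    return out


def bin_genes(
    track_0: LesionTrack,
    track_t: LesionTrack,
    genes: pd.DataFrame,
    normalizer: Normalizer,
    n_bins: int = CODING_BINS,
    flank_bins: int = FLANK_BINS,
    flank_width: int = FLANK_WIDTH,
) -> pd.DataFrame:
    """Binned strand profile: rows (bin, strand_class) with aggregated counts
    n0/nt and the normalized fraction remaining.

    Genes shorter than ``n_bins`` bp are excluded (logged).  Bin spans that
    run off a chromosome end contribute only their in-range part.
    """
    labels = (
        [f"up{i}" for i in range(flank_bins, 0, -1)]
        + [f"b{i}" for i in range(1, n_bins + 1)]
        + [f"dn{i}" for i in range(1, flank_bins + 1)]
    )
    n0 = {(lbl, sc): 0 for lbl in labels for sc in ("TS", "NTS")}
    nt = {k: 0 for k in n0}
    excluded = 0
    for _, gene in genes.iterrows():
        try:
            bins = gene_bins(
                int(gene["tss"]), int(gene["tes"]), gene["strand"],
                n_bins=n_bins, flank_bins=flank_bins, flank_width=flank_width,
            )
        except ValueError:
            excluded += 1
            continue
        chrom = gene["chrom"]
        ts = template_strand(gene["strand"])
        nts = gene["strand"]
        for lbl, a, b in bins:
            n0[(lbl, "TS")] += track_0.region_sum(chrom, ts, a, b)
            nt[(lbl, "TS")] += track_t.region_sum(chrom, ts, a, b)
            n0[(lbl, "NTS")] += track_0.region_sum(chrom, nts, a, b)
            nt[(lbl, "NTS")] += track_t.region_sum(chrom, nts, a, b)
    if excluded:
        logger.info("excluded %d genes too short to bin", excluded)
    rows = []
    for lbl in labels:
        for sc in ("TS", "NTS"):
            a, b = n0[(lbl, sc)], nt[(lbl, sc)]
            rows.append(
                {
                    "bin": lbl,
                    "strand_class": sc,
                    "n0": a,
                    "nt": b,
                    "fraction": normalizer.fraction(a, b) if a > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def log2_asymmetry(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-bin log2(f_TS / f_NTS); bins with a zero or missing fraction on
    either strand are reported as missing."""
    wide = profile.pivot(index="bin", columns="strand_class", values="fraction")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(wide["TS"] / wide["NTS"])
    ratio[(wide["TS"] <= 0) | (wide["NTS"] <= 0)] = np.nan
    out = ratio.reset_index().rename(columns={0: "log2_ts_nts"})
    out.columns = ["bin", "log2_ts_nts"]
    order = {lbl: i for i, lbl in enumerate(BIN_ORDER)}
    return out.sort_values("bin", key=lambda s: s.map(order)).reset_index(drop=True)


@dataclass(frozen=True)
class PairedTestResult:
    pvalue: float
    degenerate: bool = False


def paired_bin_test(profile: pd.DataFrame, n_bins: int = CODING_BINS) -> PairedTestResult:
    """Two-sided paired t-test on the coding-bin (TS, NTS) fraction pairs."""
    wide = profile.pivot(index="bin", columns="strand_class", values="fraction")
    coding = wide.loc[[f"b{i}" for i in range(1, n_bins + 1)]]
    d = (coding["TS"] - coding["NTS"]).to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("coding bins contain missing fractions")
    if np.allclose(d, 0):
        return PairedTestResult(1.0)
    if np.allclose(d, d[0]):
        # constant nonzero difference: zero variance, p below machine epsilon
        return PairedTestResult(np.finfo(float).tiny, degenerate=True)
    res = stats.ttest_rel(coding["TS"], coding["NTS"])
    return PairedTestResult(float(res.pvalue))


def stratify_by_transcription(
    genes: pd.DataFrame, high: float = 10.0, low: float = 1.0
) -> dict[str, pd.DataFrame]:
    """Cohorts: high (rate > 10 mRNA/h), low (rate < 1 mRNA/h), intermediate.

    Genes with a missing rate are excluded from stratified analyses.
    """
    rates = pd.to_numeric(genes["rate_mrna_per_h"], errors="coerce")
    present = genes[rates.notna()]
    rates = rates[rates.notna()]
    return {
        "high": present[rates > high],
        "low": present[rates < low],
        "intermediate": present[(rates >= low) & (rates <= high)],
    }


def tss_metaprofile(
    track_0: LesionTrack,
    track_t: LesionTrack,
    genes: pd.DataFrame,
    normalizer: Normalizer,
    window: tuple[int, int] = (-500, 640),
) -> pd.DataFrame:
    """TSS-aligned single-nucleotide metaprofile per strand class.

    For each offset in [window[0], window[1]] (TSS = 0, positive =
    downstream in the gene's frame; minus-strand genes mirrored), counts are
    summed across genes and the normalized fraction computed.  Gene/offset
    combinations falling off a chromosome are skipped.
    """
    offsets = np.arange(window[0], window[1] + 1)
    acc0 = {sc: np.zeros(len(offsets), dtype=np.int64) for sc in ("TS", "NTS")}
    acct = {sc: np.zeros(len(offsets), dtype=np.int64) for sc in ("TS", "NTS")}
    for _, gene in genes.iterrows():
        chrom = gene["chrom"]
        L = track_0.genome.lengths[chrom]
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            pos = tss + offsets
        else:
            pos = tss - offsets
        ok = (pos >= 1) & (pos <= L)
        ts, nts = template_strand(gene["strand"]), gene["strand"]
        for sc, strand in (("TS", ts), ("NTS", nts)):
            c0 = track_0.counts[(chrom, strand)]
            ct = track_t.counts[(chrom, strand)]
            acc0[sc][ok] += c0[pos[ok] - 1]
            acct[sc][ok] += ct[pos[ok] - 1]
    rows = []
    for sc in ("TS", "NTS"):
        frac = normalizer.fraction(acc0[sc], acct[sc])
        for i, off in enumerate(offsets):
            rows.append(
                {
                    "offset": int(off),
                    "strand_class": sc,
                    "n0": int(acc0[sc][i]),
                    "nt": int(acct[sc][i]),
                    "fraction": frac[i],
                }
            )
    return pd.DataFrame(rows)


def gene_cluster_matrix(
    track_0: LesionTrack,
    track_t: LesionTrack,
    genes: pd.DataFrame,
    normalizer: Normalizer,
    window: tuple[int, int] = (-500, 640),
    strand_class: str = "TS",
) -> pd.DataFrame:
    """Per-gene x per-offset normalized-fraction matrix, rows sorted stably
    by descending transcription rate (heatmap-ready; rendering is out of
    scope).  Per-gene offsets with no time-0 signal are NaN."""
    offsets = np.arange(window[0], window[1] + 1)
    order = genes.sort_values("rate_mrna_per_h", ascending=False, kind="stable")
    rows = []
    index = []
    for gi, gene in order.iterrows():
        chrom = gene["chrom"]
        L = track_0.genome.lengths[chrom]
        tss = int(gene["tss"])
        pos = tss + offsets if gene["strand"] == "+" else tss - offsets
        ok = (pos >= 1) & (pos <= L)
        strand = (
            template_strand(gene["strand"]) if strand_class == "TS" else gene["strand"]
        )
        c0 = np.zeros(len(offsets), dtype=np.int64)
        ct = np.zeros(len(offsets), dtype=np.int64)
        c0[ok] = track_0.counts[(chrom, strand)][pos[ok] - 1]
        ct[ok] = track_t.counts[(chrom, strand)][pos[ok] - 1]
        frac = normalizer.fraction(c0, ct)
        frac[~ok] = np.nan
        rows.append(frac)
        index.append(gi)
    return pd.DataFrame(rows, index=index, columns=offsets)
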