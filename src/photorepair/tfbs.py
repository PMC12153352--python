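"""Repair inhibition at transcription-factor binding sites.

Per-TF statistics compare the normalized fraction of CPDs remaining in the
core binding site (offsets −4..+4 from the motif midpoint) with adjacent
flanking DNA (−100..+100 excluding the core), pooling both strands and all
sites of a TF and aggregating counts before division.  TFs with fewer than
100 CPDs in the core at either timepoint are excluded, sites within 1 kb of
a chromosome (telomere) end are removed up front, and per-position site
profiles mask offsets with fewer than 10 CPDs at either timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gel import Normalizer
from .tracks import LesionTrack

CORE_HALFWIDTH = 4
FLANK_HALFWIDTH = 100
MIN_CORE_CPDS = 100
MASK_BELOW = 10
TELOMERE_EXCLUSION_BP = 1000
OCCUPANCY_THRESHOLD = 10.0


def load_tfbs(
    table: pd.DataFrame,
    chrom_lengths: dict[str, int],
    telomere_exclusion_bp: int = TELOMERE_EXCLUSION_BP,
    offsets: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Apply per-TF midpoint offsets (exactly once) and drop sites within
    ``telomere_exclusion_bp`` of either chromosome end.

    Offsets may come from an ``offset`` column (default 0) or the
    ``offsets`` mapping TF name -> shift; the mapping wins where both exist.
    """
    sites = table.copy()
    unknown = set(sites["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        raise KeyError(f"TFBS on unknown chromosome(s): {sorted(unknown)}")
    shift = sites["offset"] if "offset" in sites.columns else pd.Series(0, index=sites.index)
    shift = pd.to_numeric(shift, errors="coerce").fillna(0).astype(int)
    if offsets:
        mapped = sites["tf"].map(offsets)
        shift = mapped.fillna(shift).astype(int)
    sites["midpoint"] = sites["midpoint"].astype(int) + shift
    sites = sites.drop(columns=["offset"], errors="ignore")
    L = sites["chrom"].map(chrom_lengths)
    dist_to_end = np.minimum(sites["midpoint"] - 1, L - sites["midpoint"])
    return sites[dist_to_end > telomere_exclusion_bp].reset_index(drop=True)


def _window_counts(track: LesionTrack, sites: pd.DataFrame, lo: int, hi: int,
                   exclude: tuple[int, int] | None = None) -> int:
    """Counts pooled over both strands and all sites within midpoint offsets
    [lo, hi], optionally excluding the sub-window [exclude]."""
    total = 0
    for _, site in sites.iterrows():
        mid = int(site["midpoint"])
        for strand in "+-":
            total += track.region_sum(site["chrom"], strand, mid + lo, mid + hi)
            if exclude is not None:
                total -= track.region_sum(
                    site["chrom"], strand, mid + exclude[0], mid + exclude[1]
                )
    return total


@dataclass
class TFRepairStat:
    tf: str
    n_sites: int
    n0_core: int
    nt_core: int
    n0_flank: int
    nt_flank: int
    f_core: float
    f_flank: float

    @property
    def delta(self) -> float:
        return self.f_core - self.f_flank


def tf_core_flank(
    track_0: LesionTrack,
    track_t: LesionTrack,
    sites: pd.DataFrame,
    normalizer: Normalizer,
    core_halfwidth: int = CORE_HALFWIDTH,
    flank_halfwidth: int = FLANK_HALFWIDTH,
    min_core_cpds: int = MIN_CORE_CPDS,
) -> TFRepairStat | None:
    """Core-vs-flank repair statistic for all sites of one TF, or ``None``
    when the TF fails the core-count filter (< ``min_core_cpds`` CPDs in the
    core at either timepoint)."""
    if sites.empty:
        return None
    tf = str(sites["tf"].iloc[0])
    c = core_halfwidth
    n0_core = _window_counts(track_0, sites, -c, c)
    nt_core = _window_counts(track_t, sites, -c, c)
    if n0_core < min_core_cpds or nt_core < min_core_cpds:
        return None
    f = flank_halfwidth
    n0_flank = _window_counts(track_0, sites, -f, f, exclude=(-c, c))
    nt_flank = _window_counts(track_t, sites, -f, f, exclude=(-c, c))
    return TFRepairStat(
        tf=tf,
        n_sites=len(sites),
        n0_core=n0_core,
        nt_core=nt_core,
        n0_flank=n0_flank,
        nt_flank=nt_flank,
        f_core=normalizer.fraction(n0_core, nt_core),
        f_flank=normalizer.fraction(n0_flank, nt_flank) if n0_flank > 0 else np.nan,
    )


def tf_scatter(
    track_0: LesionTrack,
    track_t: LesionTrack,
    sites: pd.DataFrame,
    normalizer: Normalizer,
    **kwargs,
) -> pd.DataFrame:
    """Per-TF scatter table (one row per TF passing the count filter),
    ordered by TF name for reproducibility."""
    rows = []
    for tf in sorted(sites["tf"].unique()):
        stat = tf_core_flank(track_0, track_t, sites[sites["tf"] == tf], normalizer, **kwargs)
        if stat is None:
            continue
        rows.append(
            {
                "tf": stat.tf,
                "n_sites": stat.n_sites,
                "n0_core": stat.n0_core,
                "nt_core": stat.nt_core,
                "f_core": stat.f_core,
                "f_flank": stat.f_flank,
                "delta": stat.delta,
            }
        )
    return pd.DataFrame(
        rows, columns=["tf", "n_sites", "n0_core", "nt_core", "f_core", "f_flank", "delta"]
    )


def tf_site_profile(
    track_0: LesionTrack,
    track_t: LesionTrack,
    sites: pd.DataFrame,
    normalizer: Normalizer,
    window: int = 500,
    min_cpds: int = MASK_BELOW,
) -> pd.DataFrame:
    """Per-offset aggregated fraction remaining across sites, oriented by
    motif strand (minus-strand motifs mirrored) and pooling both strands of
    the track; offsets with < ``min_cpds`` CPDs at either timepoint are
    masked (fraction reported but flagged)."""
    offsets = np.arange(-window, window + 1)
    acc0 = np.zeros(len(offsets), dtype=np.int64)
    acct = np.zeros(len(offsets), dtype=np.int64)
    genome = track_0.genome
    for _, site in sites.iterrows():
        chrom = site["chrom"]
        L = genome.lengths[chrom]
        mid = int(site["midpoint"])
        pos = mid + offsets if site.get("strand", "+") == "+" else mid - offsets
        ok = (pos >= 1) & (pos <= L)
        for strand in "+-":
            acc0[ok] += track_0.counts[(chrom, strand)][pos[ok] - 1]
            acct[ok] += track_t.counts[(chrom, strand)][pos[ok] - 1]
    frac = normalizer.fraction(acc0, acct)
    return pd.DataFrame(
        {
            "offset": offsets,
            "n0": acc0,
            "nt": acct,
            "fraction": frac,
            "masked": (acc0 < min_cpds) | (acct < min_cpds),
        }
    )


def occupancy_split(
    sites: pd.DataFrame, threshold: float = OCCUPANCY_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sites into (bound, low-occupancy control) sets: occupancy
    strictly below ``threshold`` -> control.  Sites with missing occupancy
    are excluded from both."""
    occ = pd.to_numeric(sites["occupancy"], errors="coerce")
    present = sites[occ.notna()]
    occ = occ[occ.notna()]
    return (
        present[occ >= threshold].reset_index(drop=True),
        present[occ < threshold].reset_index(drop=True),
    )
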