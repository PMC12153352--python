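"""Single-nucleotide CPD lesion calling from aligned damage-seq reads.

The library chemistry ligates the second adapter to the 3'-OH created
immediately upstream of the cleaved lesion, so the lesion lies in the two
bases immediately upstream of the sequencing read's 5' end, on the opposite
strand:

* plus-strand read with 1-based 5' end ``p``  -> candidate lesion on the
  minus strand covering plus-coordinates (p-2, p-1), keyed ``p-1`` (the
  lesion's 5'-most base on the minus strand); dinucleotide (5'->3' on the
  minus strand) = complement(base p-1), complement(base p-2).
* minus-strand read with 1-based 5' end ``q`` (its rightmost coordinate)
  -> candidate lesion on the plus strand at (q+1, q+2), keyed ``q+1``.

Reads whose candidate dinucleotide is not one of TT/TC/CT/CC are filtered;
reads whose upstream window falls off the chromosome end, or whose window
contains an ambiguous base, are dropped and tallied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DIPYRIMIDINES, Genome
from .tracks import LesionTrack

logger = logging.getLogger(__name__)


@dataclass
class CallStats:
    """Tally of read fates during lesion calling."""

    retained: int = 0
    non_dipyrimidine: int = 0
    off_end: int = 0
    ambiguous: int = 0
    by_dinucleotide: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.retained + self.non_dipyrimidine + self.off_end + self.ambiguous


def call_lesion(
    genome: Genome, chrom: str, start: int, end: int, strand: str
) -> tuple[str, int, str] | None:
    """Call the candidate lesion for one aligned read.

    ``start``/``end`` are 0-based half-open as on disk (BED).  Returns
    ``(lesion_strand, position, dinucleotide)`` with a 1-based position
    keyed by the leftmost plus-strand base of the dinucleotide, or ``None``
    if the read is filtered (non-dipyrimidine, off-end, or ambiguous base).
    """
    if chrom not in genome:
        raise KeyError(f"read on unknown chromosome {chrom!r}")
    if start >= end:
        raise ValueError(f"bad read interval {start}-{end}")
    L = genome.lengths[chrom]
    if strand == "+":
        p = start + 1  # 1-based 5' end
        key = p - 1
        lesion_strand = "-"
        if key - 1 < 1 or key > L:
            return None
    elif strand == "-":
        q = end  # 1-based 5' end of a minus-strand read
        key = q + 1
        lesion_strand = "+"
        if key < 1 or key + 1 > L:
            return None
    else:
        raise ValueError(f"bad read strand {strand!r}")
    dinuc = genome.dinucleotide(chrom, lesion_strand, key)
    if dinuc not in DIPYRIMIDINES:
        return None
    return lesion_strand, key, dinuc


def build_track(reads: pd.DataFrame, genome: Genome, **metadata) -> tuple[LesionTrack, CallStats]:
    """Aggregate aligned reads of one library into a zero-filled lesion track.

    ``reads`` must carry columns ``chrom, start, end, strand`` (0-based
    half-open, as read from BED).  Returns the track (metadata records the
    retained-read total N) and per-fate tallies.
    """
    track = LesionTrack.zeros(genome, **metadata)
    stats = CallStats()
    unknown = set(reads["chrom"].unique()) - set(genome.chrom_names)
    if unknown:
        raise KeyError(f"reads on unknown chromosome(s): {sorted(unknown)}")
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=False):
        L = genome.lengths[chrom]
        b = genome.bytes(chrom)
        if strand == "+":
            keys = grp["start"].to_numpy(dtype=np.int64)  # p - 1
            lesion_strand = "-"
            in_range = (keys >= 2) & (keys <= L)
        elif strand == "-":
            keys = grp["end"].to_numpy(dtype=np.int64) + 1  # q + 1
            lesion_strand = "+"
            in_range = (keys >= 1) & (keys + 1 <= L)
        else:
            raise ValueError(f"bad read strand {strand!r}")
        stats.off_end += int((~in_range).sum())
        keys = keys[in_range]
        if lesion_strand == "-":
            ambiguous = (b[keys - 2] == b"N") | (b[keys - 1] == b"N")
        else:
            ambiguous = (b[keys - 1] == b"N") | (b[keys] == b"N")
        stats.ambiguous += int(ambiguous.sum())
        keys = keys[~ambiguous]
        mask = genome.dipy_mask(chrom, lesion_strand)
        is_dipy = mask[keys - 1]
        stats.non_dipyrimidine += int((~is_dipy).sum())
        keys = keys[is_dipy]
        stats.retained += len(keys)
        np.add.at(track.counts[(chrom, lesion_strand)], keys - 1, 1)
    track.metadata["n_retained"] = stats.retained
    if stats.off_end or stats.ambiguous:
        logger.info(
            "dropped %d off-end and %d ambiguous-base reads",
            stats.off_end,
            stats.ambiguous,
        )
    comp = dinucleotide_composition(None, track=track)
    stats.by_dinucleotide = comp
    return track, stats


def dinucleotide_composition(genome: Genome | None, track: LesionTrack) -> dict[str, int]:
    """Count retained lesions by dinucleotide class (TT/TC/CT/CC).

    The four categories sum to the track's N (every retained lesion sits at
    a dipyrimidine by construction).
    """
    genome = genome or track.genome
    out = {d: 0 for d in DIPYRIMIDINES}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for (chrom, strand), arr in track.counts.items():
        idx = np.nonzero(arr)[0]
        if len(idx) == 0:
            continue
        b = genome.bytes(chrom)
        if strand == "+":
            duplex = np.char.add(b[idx].astype("U1"), b[idx + 1].astype("U1"))
        else:
            # key is the 5'-most minus-strand base: plus coords (key-1, key)
            duplex = np.array(
                [comp[y] + comp[x]
                 for x, y in zip(b[idx - 1].astype("U1"), b[idx].astype("U1"))]
            )
        for d, n in zip(duplex, arr[idx]):
            if d in out:
                out[d] += int(n)
    return out
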