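"""Strand-resolved single-nucleotide lesion-count tracks.

A :class:`LesionTrack` stores, per chromosome and strand, a dense integer
count array over the whole chromosome in which every genomic dipyrimidine
position is present (zero-filled when no lesion mapped there) and every
non-dipyrimidine position is structurally zero.  Positions are keyed by the
leftmost plus-strand coordinate of the dinucleotide (see
:mod:`photorepair.genome`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Genome

STRANDS = ("+", "-")


@dataclass
class LesionTrack:
    genome: Genome
    counts: dict[tuple[str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, genome: Genome, **metadata) -> "LesionTrack":
        counts = {
            (chrom, strand): np.zeros(length, dtype=np.int64)
            for chrom, length in genome.lengths.items()
            for strand in STRANDS
        }
        return cls(genome=genome, counts=counts, metadata=metadata)

    # -- totals ------------------------------------------------------------
    @property
    def N(self) -> int:
        """Total retained reads/lesions (sum of all counts)."""
        return int(sum(arr.sum() for arr in self.counts.values()))

    def strand_counts(self, chrom: str, strand: str) -> np.ndarray:
        return self.counts[(chrom, strand)]

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        """Add ``n`` lesions at 1-based position ``pos`` on ``strand``."""
        self.counts[(chrom, strand)][pos - 1] += n

    def region_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Sum of counts over 1-based inclusive [start, end], clipped to the
        chromosome."""
        arr = self.counts[(chrom, strand)]
        lo = max(start - 1, 0)
        hi = min(end, len(arr))
        if hi <= lo:
            return 0
        return int(arr[lo:hi].sum())

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        """Assert structural invariants: non-negative integer counts confined
        to dipyrimidine positions of the matching strand."""
        for (chrom, strand), arr in self.counts.items():
            if (arr < 0).any():
                raise ValueError(f"negative counts on {chrom}{strand}")
            mask = self.genome.dipy_mask(chrom, strand)
            if arr[~mask].any():
                raise ValueError(
                    f"counts at non-dipyrimidine positions on {chrom}{strand}"
                )

    def nonzero(self):
        """Yield (chrom, strand, pos_1based, count) for every hit site."""
        for (chrom, strand), arr in self.counts.items():
            idx = np.nonzero(arr)[0]
            for i in idx:
                yield chrom, strand, int(i) + 1, int(arr[i])

    def copy(self) -> "LesionTrack":
        return LesionTrack(
            genome=self.genome,
            counts={k: v.copy() for k, v in self.counts.items()},
            metadata=dict(self.metadata),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LesionTrack):
            return NotImplemented
        if set(self.counts) != set(other.counts):
            return False
        return all(np.array_equal(self.counts[k], other.counts[k]) for k in self.counts)
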