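"""Genome container with strand-resolved dipyrimidine site masks.

Coordinates are 1-based inclusive throughout the library; the BED layer in
:mod:`photorepair.io` converts to/from 0-based half-open on disk.

A dinucleotide is keyed by the plus-strand coordinate of its 5'-most base
on its own strand.  A plus-strand dipyrimidine at key ``i`` covers plus
coordinates (i, i+1), both pyrimidines (C/T); a minus-strand dipyrimidine
at key ``i`` covers plus coordinates (i-1, i), both purines (A/G) on the
plus strand (so their minus-strand complements are pyrimidines).  This
convention makes reverse-complement mirroring an exact coordinate map
(position p -> L+1-p with strands swapped).
"""

from __future__ import annotations

import numpy as np

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
DIPYRIMIDINES = ("TT", "TC", "CT", "CC")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """In-memory genome: chromosome name -> uppercase sequence.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to DNA sequence (A/C/G/T, N tolerated).
    seed
        Optional provenance seed recorded by the synthetic generator.
    """

    def __init__(self, sequences: dict[str, str], seed: int | None = None):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            s = seq.upper()
            if not s:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if set(s) - set("ACGTN"):
                bad = sorted(set(s) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} has invalid bases {bad}")
            self.sequences[name] = s
        self.seed = seed
        self._byte_cache: dict[str, np.ndarray] = {}
        self._mask_cache: dict[tuple[str, str], np.ndarray] = {}

    # -- basic accessors ---------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def seq(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        """Plus-strand sequence of ``chrom`` over 1-based inclusive [start, end]."""
        s = self.sequences[chrom]
        if start is None:
            return s
        if start < 1 or end > len(s) or start > end:
            raise ValueError(f"bad range {start}-{end} on {chrom} (len {len(s)})")
        return s[start - 1 : end]

    def bytes(self, chrom: str) -> np.ndarray:
        """Sequence as a read-only ``S1`` numpy array (0-based index)."""
        if chrom not in self._byte_cache:
            arr = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype="S1")
            arr.flags.writeable = False
            self._byte_cache[chrom] = arr
        return self._byte_cache[chrom]

    # -- dipyrimidine machinery -------------------------------------------
    def dipy_mask(self, chrom: str, strand: str) -> np.ndarray:
        """Boolean array of length L; index i-1 is True iff a dipyrimidine on
        ``strand`` has its 5'-most base at 1-based plus-coordinate i."""
        key = (chrom, strand)
        if key not in self._mask_cache:
            b = self.bytes(chrom)
            mask = np.zeros(len(b), dtype=bool)
            if strand == "+":
                is_member = (b == b"C") | (b == b"T")
                mask[:-1] = is_member[:-1] & is_member[1:]
            elif strand == "-":
                is_member = (b == b"A") | (b == b"G")
                mask[1:] = is_member[:-1] & is_member[1:]
            else:
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            mask.flags.writeable = False
            self._mask_cache[key] = mask
        return self._mask_cache[key]

    def dinucleotide(self, chrom: str, strand: str, pos: int) -> str:
        """Dinucleotide read 5'->3' on ``strand`` whose 5'-most base is at
        1-based plus-coordinate ``pos`` (plus: covers pos..pos+1; minus:
        covers pos-1..pos)."""
        if strand == "+":
            return self.seq(chrom, pos, pos + 1)
        return revcomp(self.seq(chrom, pos - 1, pos))

    def n_dipy_sites(self) -> int:
        return int(
            sum(self.dipy_mask(c, s).sum() for c in self.sequences for s in "+-")
        )

    def __repr__(self) -> str:  # pragma: no cover
        total = sum(self.lengths.values())
        return f"Genome({len(self.sequences)} chroms, {total} bp)"
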