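"""Disk formats: FASTA genomes, BED6 reads, wiggle/bedGraph count tracks,
gel-lane TSVs and run configs.

The library works in 1-based inclusive coordinates; BED files on disk are
0-based half-open.  All text I/O is gzip-transparent (by file extension).
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gel import GelLane
from .genome import Genome
from .tracks import LesionTrack

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Genome:
    try:
        from pyfaidx import Fasta

        fa = Fasta(str(path), rebuild=False, build_index=False)
        return Genome({name: str(fa[name][:]) for name in fa.keys()})
    except Exception:
        # .gz or unindexed input: plain parse
        seqs: dict[str, list[str]] = {}
        name = None
        with _open(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    seqs[name] = []
                else:
                    seqs[name].append(line)
        return Genome({k: "".join(v) for k, v in seqs.items()})


# -- BED --------------------------------------------------------------------

def write_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


def read_bed(path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", header=None, comment="#")
    reads = reads.iloc[:, : len(BED_COLUMNS)]
    reads.columns = BED_COLUMNS[: reads.shape[1]]
    if "strand" not in reads.columns:
        raise ValueError("BED input must have 6 columns (strand required)")
    return reads


# -- count tracks -----------------------------------------------------------

def write_track(track: LesionTrack, prefix, fmt: str = "bedgraph") -> list[Path]:
    """Write per-strand count tracks as bedGraph (sparse) or fixed-step-1
    wiggle over dipyrimidine positions (zero-filled)."""
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = Path(f"{prefix}.{tag}.{'bedgraph' if fmt == 'bedgraph' else 'wig'}")
        with _open(path, "wt") as fh:
            for chrom in track.genome.chrom_names:
                arr = track.counts[(chrom, strand)]
                if fmt == "bedgraph":
                    mask = track.genome.dipy_mask(chrom, strand)
                    idx = np.nonzero(mask)[0]
                    for i in idx:
                        fh.write(f"{chrom}\t{i}\t{i + 1}\t{arr[i]}\n")
                elif fmt == "wig":
                    fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                    fh.write("\n".join(str(int(v)) for v in arr) + "\n")
                else:
                    raise ValueError(f"unknown track format {fmt!r}")
        paths.append(path)
    return paths


# -- gel lanes --------------------------------------------------------------

def write_gel_lanes(lanes: list[GelLane], path) -> None:
    rows = []
    for lane in lanes:
        if lane.fragment_lengths is None:
            raise ValueError("only raw fragment-length lanes are written as TSV")
        for fl in lane.fragment_lengths:
            rows.append((lane.lane, lane.treatment, lane.timepoint, fl))
    pd.DataFrame(
        rows, columns=["lane", "treatment", "timepoint", "fragment_length"]
    ).to_csv(path, sep="\t", index=False)


def read_gel_lanes(path) -> list[GelLane]:
    table = pd.read_csv(path, sep="\t")
    lanes = []
    for (lane, treatment, t), grp in table.groupby(["lane", "treatment", "timepoint"]):
        lanes.append(
            GelLane(
                lane=str(lane),
                treatment=str(treatment),
                timepoint=float(t),
                fragment_lengths=grp["fragment_length"].to_numpy(dtype=float),
            )
        )
    return lanes


# -- configs and provenance -------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance_header(config: dict | None = None, seed: int | None = None) -> str:
    parts = [f"# photorepair v{__version__}"]
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, config: dict | None = None, seed: int | None = None) -> None:
    """TSV with a one-line provenance comment header."""
    with _open(path, "wt") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
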