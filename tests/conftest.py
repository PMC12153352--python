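"""Shared synthetic fixtures (session-scoped where generation is costly)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from photorepair import gel, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def genome():
    return synth.make_genome(seed=11, n_chrom=1, length=100_000, gc=0.40)


@pytest.fixture(scope="session")
def annotations(genome):
    return synth.make_annotations(
        genome,
        n_genes=24,
        n_dyads=120,
        tf_specs=[
            {"tf": "Reb1", "n_sites": 8, "occupancy": 50.0},
            {"tf": "Hap3", "n_sites": 6, "occupancy": 5.0},
        ],
        seed=12,
    )


@pytest.fixture(scope="session")
def damage(genome):
    return synth.simulate_damage(genome, dose_scale=0.25, seed=13)


@pytest.fixture(scope="session")
def occluded_experiment(genome, annotations, damage):
    """Repair with transcribed-strand occlusion, nucleosome and TFBS effects."""
    model = synth.RepairRateModel(
        ts_occlusion=0.5,
        nuc_rotational_amp=0.3,
        nuc_rotational_phase=2.0,
        nuc_3prime_attenuation=0.6,
        tfbs_block=0.8,
    )
    return synth.simulate_repair(damage, model, annotations, [0, 30, 60], "rad14+PR", seed=14)


@pytest.fixture(scope="session")
def symmetric_experiment(genome, annotations, damage):
    """Strand-symmetric null: uniform photolyase rate, no context effects."""
    model = synth.RepairRateModel(
        ts_occlusion=1.0,
        ner_ts_boost=1.0,
        nuc_translational_depth=0.0,
        nuc_rotational_amp=0.0,
        nuc_3prime_attenuation=1.0,
        tfbs_block=0.0,
    )
    return synth.simulate_repair(damage, model, annotations, [0, 30], "rad14+PR", seed=15)


@pytest.fixture
def anchored(occluded_experiment):
    """(track0, track30, normalizer) for the occluded experiment."""
    t0 = occluded_experiment.lesions_t0
    tt = occluded_experiment.surviving_lesions[30]
    norm = gel.gel_anchor(t0, tt, occluded_experiment.true_fraction_remaining[30])
    return t0, tt, norm


def mirror_genome(genome):
    """Reverse-complement every chromosome (test helper)."""
    from photorepair.genome import Genome, revcomp

    return Genome({c: revcomp(s) for c, s in genome.sequences.items()})


def mirror_track(track, mirrored_genome):
    """Map a lesion track onto the reverse-complemented genome.

    With lesions keyed by their 5'-most base, mirroring is the exact
    coordinate map p -> L+1-p with strands swapped.
    """
    from photorepair.tracks import LesionTrack

    out = LesionTrack.zeros(mirrored_genome, **track.metadata)
    for (chrom, strand), arr in track.counts.items():
        out.counts[(chrom, "-" if strand == "+" else "+")] = arr[::-1].copy()
    return out


def mirror_genes(genes, lengths):
    out = genes.copy()
    L = out["chrom"].map(lengths)
    out["tss"] = L + 1 - out["tss"]
    out["tes"] = L + 1 - out["tes"]
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out
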