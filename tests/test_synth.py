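"""Synthetic-data generator contracts: determinism, conservation, closed
forms, and the read/lesion round trip."""

import numpy as np
import pandas as pd
import pytest

from photorepair import calling, synth
from photorepair.genome import DIPYRIMIDINES


# -- genomes ----------------------------------------------------------------

def test_make_genome_deterministic_and_seed_sensitive():
    a = synth.make_genome(1, length=5000, gc=0.38)
    b = synth.make_genome(1, length=5000, gc=0.38)
    c = synth.make_genome(2, length=5000, gc=0.38)
    assert a.sequences == b.sequences
    assert a.sequences != c.sequences


def test_make_genome_gc_zero_is_all_at():
    g = synth.make_genome(3, length=2000, gc=0.0)
    seq = g.seq("chr1")
    assert set(seq) <= {"A", "T"}
    # every TT pair is a plus-strand site (keyed left) and every AA pair a
    # minus-strand site (keyed right)
    for i in range(len(seq) - 1):
        duo = seq[i : i + 2]
        assert g.dipy_mask("chr1", "+")[i] == (duo == "TT")
        assert g.dipy_mask("chr1", "-")[i + 1] == (duo == "AA")


def test_make_genome_validates_inputs():
    with pytest.raises(ValueError):
        synth.make_genome(1, length=10)
    with pytest.raises(ValueError):
        synth.make_genome(1, length=5000, gc=1.5)


# -- annotations ------------------------------------------------------------

def test_annotation_cohorts_and_thresholds(genome):
    ann = synth.make_annotations(
        genome, n_genes=10, n_dyads=20, seed=5,
        gene_rates=[0.1, 20], dyad_scores=[1, 10],
        tf_specs=[{"tf": "Reb1", "n_sites": 4, "occupancy": [5, 50, 5, 50]}],
    )
    rates = ann.genes["rate_mrna_per_h"]
    assert (rates > 10).sum() == 5 and (rates < 1).sum() == 5
    assert (ann.dyads["score"] > 5).sum() == 10
    assert (ann.tfbs["occupancy"] < 10).sum() == 2


def test_annotation_packing_infeasible():
    g = synth.make_genome(4, length=2000)
    with pytest.raises(ValueError, match="infeasible"):
        synth.make_annotations(g, n_genes=10, n_dyads=0, seed=1)


# -- damage induction -------------------------------------------------------

def test_damage_respects_propensities(genome):
    zero_cc = synth.simulate_damage(
        genome, 0.5, {"TT": 1, "TC": 1, "CT": 1, "CC": 0}, seed=6
    )
    comp = calling.dinucleotide_composition(genome, zero_cc)
    assert comp["CC"] == 0 and comp["TT"] > 0
    empty = synth.simulate_damage(genome, 0.0, seed=6)
    assert empty.N == 0
    empty.validate()  # zero-filled background still structurally valid


def test_damage_tt_ct_ratio_matches_poisson_oracle(genome):
    """With TT weight 10x CT, lesion totals scale as 10x the site ratio."""
    track = synth.simulate_damage(
        genome, 0.3, {"TT": 1.0, "TC": 0.0, "CT": 0.1, "CC": 0.0}, seed=7
    )
    comp = calling.dinucleotide_composition(genome, track)
    sites = {d: 0 for d in DIPYRIMIDINES}
    for chrom in genome.chrom_names:
        for strand in "+-":
            idx = np.nonzero(genome.dipy_mask(chrom, strand))[0]
            for i in idx:
                sites[genome.dinucleotide(chrom, strand, int(i) + 1)] += 1
    expect_tt = 0.3 * 1.0 * sites["TT"]
    expect_ct = 0.3 * 0.1 * sites["CT"]
    ratio = comp["TT"] / comp["CT"]
    expected = expect_tt / expect_ct
    # delta-method sigma for a Poisson-count ratio
    sigma = expected * np.sqrt(1 / expect_tt + 1 / expect_ct)
    assert abs(ratio - expected) < 3 * sigma


# -- repair -----------------------------------------------------------------

def test_double_mutant_has_no_repair(damage, annotations):
    exp = synth.simulate_repair(
        damage, synth.RepairRateModel(), annotations, [30, 120], "rad14phr1+PR", seed=8
    )
    for t in (30, 120):
        assert exp.surviving_lesions[t] == damage
        assert exp.true_fraction_remaining[t] == 1.0


def test_uniform_rate_half_life(damage, annotations):
    model = synth.RepairRateModel(
        base_rate_photolyase=0.02, base_rate_ner=0.0,
        ts_occlusion=1.0, ner_ts_boost=1.0, nuc_translational_depth=0.0,
    )
    t_half = np.log(2) / 0.02
    exp = synth.simulate_repair(damage, model, annotations, [t_half], "rad14+PR", seed=9)
    f = exp.true_fraction_remaining[t_half]
    n = damage.N
    sigma = np.sqrt(0.5 * 0.5 / n)
    assert abs(f - 0.5) < 3 * sigma


def test_surviving_counts_never_exceed_t0(occluded_experiment):
    t0 = occluded_experiment.lesions_t0
    for t, trk in occluded_experiment.surviving_lesions.items():
        for key in t0.counts:
            assert (trk.counts[key] <= t0.counts[key]).all()
        assert trk.N == pytest.approx(
            occluded_experiment.true_fraction_remaining[t] * t0.N
        )


def test_ts_occlusion_slows_template_strand(occluded_experiment, annotations):
    """Closed-form check: with photolyase rate halved on the TS, the TS
    retains more lesions than the NTS in gene bodies at every t > 0."""
    from photorepair.annotations import gene_body, template_strand

    t0 = occluded_experiment.lesions_t0
    for t in (30, 60):
        trk = occluded_experiment.surviving_lesions[t]
        ts0 = nts0 = ts_t = nts_t = 0
        for _, gene in annotations.genes.iterrows():
            lo, hi = gene_body(gene)
            ts = template_strand(gene["strand"])
            nts = gene["strand"]
            ts0 += t0.region_sum(gene["chrom"], ts, lo, hi)
            ts_t += trk.region_sum(gene["chrom"], ts, lo, hi)
            nts0 += t0.region_sum(gene["chrom"], nts, lo, hi)
            nts_t += trk.region_sum(gene["chrom"], nts, lo, hi)
        assert ts_t / ts0 > nts_t / nts0


def test_unknown_strain_rejected(damage, annotations):
    with pytest.raises(ValueError, match="unknown strain"):
        synth.simulate_repair(damage, synth.RepairRateModel(), annotations, [30], "xrcc1", seed=0)


# -- reads ------------------------------------------------------------------

def test_round_trip_is_exact_identity(occluded_experiment):
    surviving = occluded_experiment.surviving_lesions[30]
    reads, skipped = synth.lesions_to_reads(surviving, 0.0, seed=10)
    track, stats = calling.build_track(reads, surviving.genome)
    assert skipped == 0
    assert stats.non_dipyrimidine == 0
    assert track == surviving


def test_minus_strand_lesion_read_placement():
    from photorepair.genome import Genome
    from photorepair.tracks import LesionTrack

    g = Genome({"c": "GGAAGGGGGGGG"})
    t = LesionTrack.zeros(g)
    t.add("c", "-", 4)  # minus-strand TT over plus positions 3-4, keyed 4
    reads, _ = synth.lesions_to_reads(t, 0.0, read_length=5, seed=0)
    assert len(reads) == 1
    row = reads.iloc[0]
    assert row["strand"] == "+"
    assert row["start"] + 1 == 5  # 1-based 5' end at position 5


def test_decoy_fraction(occluded_experiment):
    surviving = occluded_experiment.surviving_lesions[30]
    n = surviving.N
    reads, _ = synth.lesions_to_reads(surviving, 0.2, seed=11)
    track, stats = calling.build_track(reads, surviving.genome)
    assert stats.retained == n  # every true lesion recovered
    assert stats.non_dipyrimidine == round(n * 0.2 / 0.8)
    assert track == surviving


def test_lesion_counts_emit_multiple_reads():
    from photorepair.genome import Genome
    from photorepair.tracks import LesionTrack

    g = Genome({"c": "G" * 30 + "TT" + "G" * 30})
    t = LesionTrack.zeros(g)
    t.add("c", "+", 31, 3)
    reads, _ = synth.lesions_to_reads(t, 0.0, read_length=10, seed=0)
    assert len(reads) == 3


# -- gel lanes --------------------------------------------------------------

def test_gel_density_zero_gives_full_length_fragments():
    lanes = synth.simulate_gel_lanes({0: 0.0}, molecule_length=50_000, n_molecules=50, seed=12)
    t4 = next(l for l in lanes if l.treatment == "t4")
    assert np.all(t4.fragment_lengths == 50_000)


def test_gel_number_average_matches_renewal_oracle():
    """Poisson cleavage at rate phi: number-average length = 1/(phi/1000 + 1/L)."""
    lanes = synth.simulate_gel_lanes({0: 0.5}, molecule_length=50_000, n_molecules=10_000, seed=13)
    t4 = next(l for l in lanes if l.treatment == "t4")
    expected = 1.0 / (0.5 / 1000 + 1.0 / 50_000)
    assert np.mean(t4.fragment_lengths) == pytest.approx(expected, rel=0.05)


def test_gel_doubling_density_shortens_fragments():
    mean_len = []
    for phi in (0.25, 0.5, 1.0):
        lanes = synth.simulate_gel_lanes({0: phi}, n_molecules=2000, seed=14)
        t4 = next(l for l in lanes if l.treatment == "t4")
        mean_len.append(np.mean(t4.fragment_lengths))
    assert mean_len[0] > mean_len[1] > mean_len[2]


# -- passaging mutations ----------------------------------------------------

def test_passaging_null_ts_fold(genome, annotations):
    from photorepair import mutations as mut

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=20, mean_per_isolate=120, ts_fold=1.0, seed=15
    )
    dist = mut.gene_body_distribution(recs, annotations.genes, genome)
    fold = mut.ts_nts_fold(dist)
    assert 0.7 < fold < 1.4


def test_recurrent_fraction_removed_by_unique_filter(genome, annotations):
    from photorepair import mutations as mut

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=20, mean_per_isolate=100,
        ts_fold=1.0, recurrent_fraction=0.1, seed=16,
    )
    uniq = mut.unique_filter(recs)
    removed = 1 - len(uniq) / len(recs)
    # configured 10% plus a small birthday-collision excess
    assert 0.07 < removed < 0.16


def test_generator_determinism(genome, annotations):
    a = synth.simulate_passaging_mutations(annotations, genome, n_isolates=5, seed=17)
    b = synth.simulate_passaging_mutations(annotations, genome, n_isolates=5, seed=17)
    pd.testing.assert_frame_equal(a, b)
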