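"""Gel quantification, replicate statistics, and the normalization anchor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photorepair import gel, synth


# -- lane lengths -----------------------------------------------------------

def test_ladder_log_linear_interpolation():
    lane = gel.GelLane(
        lane="a", treatment="t4", timepoint=0,
        profile=pd.DataFrame({"distance_mm": [15.0], "intensity": [1.0]}),
        ladder=pd.DataFrame({"distance_mm": [10.0, 20.0], "length": [23130.0, 2027.0]}),
    )
    # midpoint in log space: sqrt(23130 * 2027) ~ 6847 nt
    assert gel.lane_fragment_length(lane) == pytest.approx(np.sqrt(23130 * 2027), rel=1e-6)


def test_median_outside_ladder_is_error():
    lane = gel.GelLane(
        lane="a", treatment="t4", timepoint=0,
        profile=pd.DataFrame({"distance_mm": [25.0], "intensity": [1.0]}),
        ladder=pd.DataFrame({"distance_mm": [10.0, 20.0], "length": [23130.0, 2027.0]}),
    )
    with pytest.raises(ValueError, match="outside ladder"):
        gel.lane_fragment_length(lane)


def test_raw_lengths_number_average():
    lane = gel.GelLane(lane="a", treatment="mock", timepoint=0,
                       fragment_lengths=np.full(100, 50_000.0))
    assert gel.lane_fragment_length(lane) == 50_000.0


def test_simulated_length_matches_renewal_theory():
    lanes = synth.simulate_gel_lanes({0: 1.0}, molecule_length=50_000,
                                     n_molecules=10_000, seed=31)
    t4 = next(l for l in lanes if l.treatment == "t4")
    expected = 1.0 / (1.0 / 1000 + 1.0 / 50_000)
    assert gel.lane_fragment_length(t4) == pytest.approx(expected, rel=0.05)


# -- density and percent repaired -------------------------------------------

def test_cpds_per_kb_arithmetic():
    assert gel.cpds_per_kb(2000, 10_000) == pytest.approx(0.4)
    assert gel.cpds_per_kb(5000, 5000) == 0.0
    with pytest.warns(UserWarning):
        assert gel.cpds_per_kb(10_000, 2000) == 0.0


def test_percent_repaired_cases():
    assert gel.percent_repaired(1.0, 1.0) == 0.0
    assert gel.percent_repaired(0.0, 1.0) == 100.0
    assert gel.percent_repaired(0.08, 1.0) == pytest.approx(92.0)
    with pytest.raises(ValueError):
        gel.percent_repaired(0.5, 0.0)


def test_density_estimator_bias_under_5pct():
    """Monte-Carlo oracle: estimate within 5% across the working range."""
    for i, phi in enumerate([0.05, 0.5, 2.0]):
        lanes = synth.simulate_gel_lanes({0: phi}, molecule_length=50_000,
                                         n_molecules=10_000, seed=40 + i)
        by = {l.treatment: gel.lane_fragment_length(l) for l in lanes}
        est = gel.cpds_per_kb(by["t4"], by["mock"])
        assert est == pytest.approx(phi, rel=0.05)


# -- replicate statistics ---------------------------------------------------

def test_replicate_test_identical_groups():
    out = gel.replicate_test({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
    assert out["p_adjusted"].iloc[0] == 1.0


def test_single_comparison_adjustment_is_identity():
    out = gel.replicate_test({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.5, 4.0]})
    assert len(out) == 1
    assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])


def test_holm_sidak_matches_stepdown_formula():
    """Independent oracle: the step-down formula
    adj_i = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1) on sorted raw p."""
    rng = np.random.default_rng(42)
    p = rng.uniform(size=7)
    order = np.argsort(p)
    m = len(p)
    adj_sorted = np.maximum.accumulate(
        [1 - (1 - p[order][j]) ** (m - j) for j in range(m)]
    )
    expected = np.empty(m)
    expected[order] = np.clip(adj_sorted, 0, 1)
    np.testing.assert_allclose(gel.holm_sidak(p), expected, rtol=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10))
def test_holm_sidak_monotone_and_dominates_raw(pvals):
    p = np.array(pvals)
    adj = gel.holm_sidak(p)
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


# -- gel anchoring ----------------------------------------------------------

def test_uniform_repair_anchors_to_f_gel(symmetric_experiment):
    t0 = symmetric_experiment.lesions_t0
    tt = symmetric_experiment.surviving_lesions[30]
    f_gel = 0.35
    norm = gel.gel_anchor(t0, tt, f_gel)
    # genome-wide aggregate: exactly F_gel by construction
    assert norm.fraction(t0.N, tt.N) == pytest.approx(f_gel, abs=1e-12)


def test_doubled_retention_region():
    norm = gel.Normalizer(f_gel=0.35, n0_total=1000, nt_total=500)
    # region with twice the average retention ratio
    assert norm.fraction(100, 100) == pytest.approx(0.70)
    assert np.isnan(norm.fraction(0, 5))


def test_two_region_recovery_of_true_survival(genome, annotations, damage):
    """Normalized per-region fractions recover exp(-kt) per region."""
    model = synth.RepairRateModel(
        base_rate_photolyase=0.02, base_rate_ner=0.0,
        ts_occlusion=0.5, nuc_translational_depth=0.0,
    )
    exp = synth.simulate_repair(damage, model, annotations, [30], "rad14+PR", seed=33)
    t0, tt = exp.lesions_t0, exp.surviving_lesions[30]
    norm = gel.gel_anchor(t0, tt, exp.true_fraction_remaining[30])
    from photorepair.annotations import gene_body, template_strand

    for strand_kind, k in (("TS", 0.02 * 0.5), ("NTS", 0.02)):
        n0 = nt = 0
        for _, gene in annotations.genes.iterrows():
            lo, hi = gene_body(gene)
            s = template_strand(gene["strand"]) if strand_kind == "TS" else gene["strand"]
            n0 += t0.region_sum(gene["chrom"], s, lo, hi)
            nt += tt.region_sum(gene["chrom"], s, lo, hi)
        f = norm.fraction(n0, nt)
        true = np.exp(-k * 30)
        sigma = np.sqrt(true * (1 - true) / n0)
        assert abs(f - true) < 4 * sigma


def test_anchor_requires_matching_tracks(genome, damage):
    other = synth.make_genome(99, length=2000)
    from photorepair.tracks import LesionTrack

    with pytest.raises(ValueError):
        gel.gel_anchor(damage, LesionTrack.zeros(other), 0.5)
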