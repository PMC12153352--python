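"""Gene-body binning, strand asymmetry, stratification and metaprofiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photorepair import gel, genes, synth

from conftest import mirror_genes, mirror_genome, mirror_track


def test_ts_nts_assignment():
    assert genes.assign_ts_nts("+", "-") == "TS"
    assert genes.assign_ts_nts("+", "+") == "NTS"
    assert genes.assign_ts_nts("-", "+") == "TS"


def test_gene_bins_worked_example():
    bins = dict((lbl, (a, b)) for lbl, a, b in genes.gene_bins(1001, 1600, "+"))
    assert bins["b1"] == (1001, 1100)
    assert bins["b6"] == (1501, 1600)
    assert bins["up1"] == (834, 1000)
    assert bins["up2"] == (667, 833)
    assert bins["up3"] == (500, 666)
    assert bins["dn1"] == (1601, 1767)


def test_gene_bins_minus_strand_abut_tss():
    bins = dict((lbl, (a, b)) for lbl, a, b in genes.gene_bins(1600, 1001, "-"))
    assert bins["b1"] == (1501, 1600)  # abuts the TSS at 1600
    assert bins["b6"] == (1001, 1100)
    assert bins["up1"] == (1601, 1767)
    assert bins["dn1"] == (834, 1000)


@settings(max_examples=40, deadline=None)
@given(
    tss=st.integers(min_value=2000, max_value=4000),
    length=st.integers(min_value=6, max_value=2500),
    strand=st.sampled_from("+-"),
)
def test_gene_bins_partition_exactly(tss, length, strand):
    tes = tss + length - 1 if strand == "+" else tss - length + 1
    bins = genes.gene_bins(tss, tes, strand)
    coding = sorted((a, b) for lbl, a, b in bins if lbl.startswith("b"))
    covered = []
    for a, b in coding:
        assert a <= b
        covered.extend(range(a, b + 1))
    lo, hi = sorted((tss, tes))
    assert covered == list(range(lo, hi + 1))  # exact tiling, no gaps/overlaps
    for lbl, a, b in bins:
        if not lbl.startswith("b"):
            assert b - a + 1 == 167


def test_too_short_gene_rejected():
    with pytest.raises(ValueError):
        genes.gene_bins(100, 104, "+")


def test_symmetric_null_bins_equal(symmetric_experiment, annotations):
    t0 = symmetric_experiment.lesions_t0
    tt = symmetric_experiment.surviving_lesions[30]
    norm = gel.gel_anchor(t0, tt, symmetric_experiment.true_fraction_remaining[30])
    prof = genes.bin_genes(t0, tt, annotations.genes, norm)
    wide = prof.pivot(index="bin", columns="strand_class", values="fraction")
    n0 = prof.pivot(index="bin", columns="strand_class", values="n0")
    for lbl in [f"b{i}" for i in range(1, 7)]:
        f = wide.loc[lbl]
        p = (f["TS"] + f["NTS"]) / 2
        sigma = np.sqrt(p * (1 - p) * (1 / n0.loc[lbl, "TS"] + 1 / n0.loc[lbl, "NTS"]))
        assert abs(f["TS"] - f["NTS"]) < 4 * sigma
    test = genes.paired_bin_test(prof)
    assert test.pvalue > 0.01


def test_occlusion_elevates_ts_in_every_coding_bin(anchored, annotations):
    t0, tt, norm = anchored
    prof = genes.bin_genes(t0, tt, annotations.genes, norm)
    wide = prof.pivot(index="bin", columns="strand_class", values="fraction")
    for lbl in [f"b{i}" for i in range(1, 7)]:
        assert wide.loc[lbl, "TS"] > wide.loc[lbl, "NTS"]
    asym = genes.log2_asymmetry(prof).set_index("bin")
    assert (asym.loc[[f"b{i}" for i in range(1, 7)], "log2_ts_nts"] > 0).all()
    assert genes.paired_bin_test(prof).pvalue < 0.05


def test_log2_asymmetry_reference_points():
    prof = pd.DataFrame(
        {
            "bin": ["b1", "b1", "b2", "b2"],
            "strand_class": ["TS", "NTS"] * 2,
            "n0": [10] * 4,
            "nt": [5] * 4,
            "fraction": [0.4, 0.4, 0.8, 0.4],
        }
    )
    out = genes.log2_asymmetry(prof).set_index("bin")["log2_ts_nts"]
    assert out["b1"] == pytest.approx(0.0)
    assert out["b2"] == pytest.approx(1.0)


def test_paired_test_degenerate_cases():
    def prof(ts, nts):
        rows = []
        for i in range(1, 7):
            rows.append({"bin": f"b{i}", "strand_class": "TS", "fraction": ts[i - 1]})
            rows.append({"bin": f"b{i}", "strand_class": "NTS", "fraction": nts[i - 1]})
        return pd.DataFrame(rows)

    same = prof([0.5] * 6, [0.5] * 6)
    assert genes.paired_bin_test(same).pvalue == 1.0
    const = prof([0.6] * 6, [0.5] * 6)
    res = genes.paired_bin_test(const)
    assert res.degenerate and res.pvalue < 1e-300


def test_stratification_thresholds():
    table = pd.DataFrame(
        {
            "chrom": ["c"] * 4, "tss": [1] * 4, "tes": [10] * 4, "strand": ["+"] * 4,
            "rate_mrna_per_h": [20.0, 0.5, 5.0, np.nan],
        }
    )
    cohorts = genes.stratify_by_transcription(table)
    assert len(cohorts["high"]) == 1 and cohorts["high"]["rate_mrna_per_h"].iloc[0] == 20
    assert len(cohorts["low"]) == 1 and cohorts["low"]["rate_mrna_per_h"].iloc[0] == 0.5
    assert len(cohorts["intermediate"]) == 1
    total = sum(len(c) for c in cohorts.values())
    assert total == 3  # the rate-less gene is excluded


def test_metaprofile_window_size_and_uniform_flatness(symmetric_experiment, annotations):
    t0 = symmetric_experiment.lesions_t0
    tt = symmetric_experiment.surviving_lesions[30]
    f_gel = symmetric_experiment.true_fraction_remaining[30]
    norm = gel.gel_anchor(t0, tt, f_gel)
    meta = genes.tss_metaprofile(t0, tt, annotations.genes, norm, window=(-500, 640))
    assert len(meta) == 2 * 1141  # 1141 offsets per strand class
    # uniform repair: profile flat at F_gel (binomial scatter only)
    frac = meta["fraction"].dropna()
    assert frac.mean() == pytest.approx(f_gel, abs=0.02)


def test_cluster_matrix_sorting_and_duplicates(anchored, annotations):
    t0, tt, norm = anchored
    mat = genes.gene_cluster_matrix(t0, tt, annotations.genes, norm, window=(-50, 100))
    rates = annotations.genes.loc[mat.index, "rate_mrna_per_h"].to_numpy()
    assert (np.diff(rates) <= 1e-12).all()  # descending, stable
    assert mat.shape[1] == 151


def test_binned_aggregate_reproduces_total(anchored, annotations):
    """Count-weighted aggregation over all bins equals the gene-set-wide
    normalized fraction exactly."""
    t0, tt, norm = anchored
    prof = genes.bin_genes(t0, tt, annotations.genes, norm)
    total_f = norm.fraction(prof["n0"].sum(), prof["nt"].sum())
    from photorepair.annotations import gene_body

    n0 = nt = 0
    for _, gene in annotations.genes.iterrows():
        for lbl, a, b in genes.gene_bins(int(gene["tss"]), int(gene["tes"]), gene["strand"]):
            for s in "+-":
                n0 += t0.region_sum(gene["chrom"], s, a, b)
                nt += tt.region_sum(gene["chrom"], s, a, b)
    assert total_f == pytest.approx(norm.fraction(n0, nt), rel=1e-12)


def test_mirror_invariance(anchored, annotations):
    """Reverse-complementing the genome and flipping annotations leaves
    every TS/NTS bin fraction unchanged."""
    t0, tt, norm = anchored
    prof = genes.bin_genes(t0, tt, annotations.genes, norm)
    mg = mirror_genome(t0.genome)
    mt0 = mirror_track(t0, mg)
    mtt = mirror_track(tt, mg)
    mgenes = mirror_genes(annotations.genes, t0.genome.lengths)
    mprof = genes.bin_genes(mt0, mtt, mgenes, norm)
    merged = prof.merge(mprof, on=["bin", "strand_class"], suffixes=("", "_m"))
    np.testing.assert_allclose(merged["fraction"], merged["fraction_m"], rtol=1e-12)
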