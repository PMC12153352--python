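"""Mutation filtering, pyrimidine-frame spectra, strand asymmetry and the
canavanine frequency arithmetic."""

import numpy as np
import pandas as pd
import pytest

from photorepair import mutations as mut
from photorepair.genome import Genome


def rec(isolate, chrom, pos, ref, alt):
    return {"isolate": isolate, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}


def test_unique_filter_removes_all_copies():
    records = pd.DataFrame(
        [
            rec("i3", "c", 10, "C", "T"),
            rec("i7", "c", 10, "C", "T"),
            rec("i1", "c", 20, "C", "A"),
        ]
    )
    out = mut.unique_filter(records)
    assert list(out["pos"]) == [20]
    kept_one = mut.unique_filter(records, keep_one=True)
    assert sorted(kept_one["pos"]) == [10, 20]


def test_validate_records_checks_reference():
    g = Genome({"c": "ACGTACGT"})
    ok = pd.DataFrame([rec("i1", "c", 2, "C", "T")])
    assert len(mut.validate_records(ok, g)) == 1
    bad = pd.DataFrame([rec("i1", "c", 2, "G", "T")])
    with pytest.raises(ValueError, match="mismatch"):
        mut.validate_records(bad, g)
    indel = pd.DataFrame([rec("i1", "c", 2, "CG", "C")])
    assert len(mut.validate_records(indel, g)) == 0


def test_pyrimidine_frame_reverse_complements_once():
    # plus strand 5'-T G A-3' with G>A: pyrimidine frame C>T in context TCA
    g = Genome({"c": "AATGAAA"})
    records = pd.DataFrame([rec("i1", "c", 4, "G", "A")])
    annotated = mut.pyrimidine_frame(records, g)
    assert annotated.loc[0, "mut_class"] == "C>T"
    assert annotated.loc[0, "context"] == "TCA"
    assert annotated.loc[0, "py_strand"] == "-"
    assert annotated.loc[0, "dipy"]  # TCA has a 5' pyrimidine neighbor


def test_spectrum_conserves_record_count(genome, annotations):
    from photorepair import synth

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=10, mean_per_isolate=60, seed=71
    )
    spectrum = mut.trinuc_spectrum(recs, genome)
    assert spectrum["count"].sum() == len(recs)
    assert spectrum.shape[0] == 96  # 6 classes x 16 contexts


def test_default_generator_channels_are_modal(genome, annotations):
    """Weights concentrated on C>T-in-dipyrimidine and T>A-in-NTA make those
    the modal channels of the recovered spectrum."""
    from photorepair import synth

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=20, mean_per_isolate=91, seed=72
    )
    spectrum = mut.trinuc_spectrum(recs, genome)
    ct_dipy = spectrum[(spectrum.mut_class == "C>T") & spectrum.dipy]["count"].sum()
    ta_nta = spectrum[
        (spectrum.mut_class == "T>A") & (spectrum.context.str[2] == "A")
    ]["count"].sum()
    others = spectrum["count"].sum() - ct_dipy - ta_nta
    assert ct_dipy > others and ta_nta > others / 2


def test_constructed_imbalance_normalizes_to_unity():
    """Oracle: a gene body where context TCA occurs 3x on the TS vs 1x on
    the NTS, with exactly one mutation placed per site, must give A = 1."""
    spacer = "AAAA"
    # gene on the plus strand => template (TS) is the minus strand.
    # TGA on the plus strand = TCA context on the minus strand (TS site);
    # TCA on the plus strand is an NTS site.
    body = spacer + "TGA" + spacer + "TGA" + spacer + "TGA" + spacer + "TCA" + spacer
    seq = "GGGG" + body + "GGGG"
    g = Genome({"c": seq})
    genes = pd.DataFrame(
        [{"chrom": "c", "tss": 5, "tes": 4 + len(body), "strand": "+",
          "rate_mrna_per_h": 5.0}]
    )
    rows = []
    for i, start in enumerate([s + 5 for s in range(len(body)) if body[s:s+3] == "TGA"]):
        # mutate the C of the minus-strand TCA: the plus-strand G
        rows.append(rec(f"i{i}", "c", start + 1, "G", "A"))
    tca_pos = 4 + body.index("TCA") + 1 + 1  # the plus-strand C
    rows.append(rec("i9", "c", tca_pos, "C", "T"))
    records = pd.DataFrame(rows)
    records = mut.validate_records(records, g)
    asym = mut.transcriptional_asymmetry(records, genes, g, min_count=0)
    row = asym[(asym.mut_class == "C>T") & (asym.context == "TCA")].iloc[0]
    assert (row.m_TS, row.m_NTS) == (3, 1)
    assert (row.k_TS, row.k_NTS) == (3, 1)
    assert row.A == pytest.approx(1.0)


def test_exclude_class_removes_exactly_nta_contexts(genome, annotations):
    from photorepair import synth

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=15, mean_per_isolate=80, seed=73
    )
    out = mut.exclude_class(recs, "T>A@NTA", genome)
    annotated = mut.pyrimidine_frame(recs, genome)
    nta = (annotated.mut_class == "T>A") & annotated.context.isin(
        ["ATA", "CTA", "GTA", "TTA"]
    )
    assert len(out) == len(annotated) - int(nta.sum())
    # identity for an empty spec
    assert len(mut.exclude_class(recs, None, genome)) == len(recs)
    rem = mut.pyrimidine_frame(out, genome)
    assert not (
        (rem.mut_class == "T>A") & rem.context.isin(["ATA", "CTA", "GTA", "TTA"])
    ).any()


def test_exclude_class_share_matches_generator(genome, annotations):
    from photorepair import synth

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=20, mean_per_isolate=100,
        class_weights={"C>T@dipy": 0.77, "T>A@NTA": 0.23}, seed=74,
    )
    out = mut.exclude_class(recs, "T>A@NTA", genome)
    share = len(out) / len(recs)
    assert share == pytest.approx(0.77, abs=0.03)


def test_gene_body_distribution_strand_assignment(genome, annotations):
    from photorepair import synth

    recs = synth.simulate_passaging_mutations(
        annotations, genome, n_isolates=20, mean_per_isolate=120, ts_fold=4.0, seed=75
    )
    dist = mut.gene_body_distribution(recs, annotations.genes, genome)
    fold = mut.ts_nts_fold(dist)
    assert 3.0 < fold < 5.3
    # intergenic mutations appear only in flank bins (or nowhere)
    coding = dist[dist["bin"].str.startswith("b")]["count"].sum()
    annotated = mut.assign_mutation_strand(
        mut.pyrimidine_frame(recs, genome), annotations.genes
    )
    in_gene = (annotated["strand_class"] != "intergenic").sum()
    assert coding == in_gene


def test_malformed_class_spec():
    g = Genome({"c": "ACGTACGT"})
    records = pd.DataFrame([rec("i1", "c", 2, "C", "T")])
    with pytest.raises(ValueError, match="malformed"):
        mut.exclude_class(records, "G>T", g)
    with pytest.raises(ValueError, match="malformed"):
        mut.exclude_class(records, "C>T@AAAA", g)


def test_canr_frequency_arithmetic():
    assert mut.canr_frequency(25, 1, 50, 1e4) == pytest.approx(5e-5)
    assert mut.fold_induction(5e-5, 1e-6) == pytest.approx(50.0)
    assert mut.fold_induction(3e-6, 3e-6) == 1.0
    with pytest.raises(ValueError):
        mut.canr_frequency(25, 1, 0, 1e4)
    with pytest.raises(ValueError):
        mut.fold_induction(1e-5, 0.0)
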