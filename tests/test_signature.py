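import math
import types

import numpy as np
import pytest

from deconvkit.signature import (
    avg_celltype_correlation,
    build_signature,
    choose_secondfc_threshold,
    compute_marker_stats,
    select_markers,
    subset_top_fraction,
)

from .conftest import make_reference_from_cpm, make_signature

THREE_GENE_PROFILES = {
    # per-type CPM of genes gA, gB, gC
    "A": [8, 5, 10],
    "B": [2, 5, 0],
    "C": [2, 5, 0],
}


@pytest.fixture(scope="module")
def three_gene_stats():
    ref = make_reference_from_cpm(THREE_GENE_PROFILES, ["gA", "gB", "gC"])
    return compute_marker_stats(ref)


class TestComputeMarkerStats:
    def test_hand_arithmetic_m_8_2_2(self, three_gene_stats):
        row = three_gene_stats.loc["gA"]
        assert row["logFC"] == pytest.approx(math.log2(9 / 3))
        assert row["SecondFC"] == pytest.approx(3.0)
        assert row["logCPM"] == pytest.approx(math.log2(5.0))
        assert row["top_type"] == "A"

    def test_symmetric_profile(self, three_gene_stats):
        row = three_gene_stats.loc["gB"]
        assert row["logFC"] == pytest.approx(0.0)
        assert row["SecondFC"] == pytest.approx(1.0)

    def test_exclusive_profile_m_10_0_0(self, three_gene_stats):
        row = three_gene_stats.loc["gC"]
        assert row["logFC"] == pytest.approx(math.log2(11.0))
        assert row["SecondFC"] == pytest.approx(11.0)

    def test_secondfc_at_least_one(self, small_ref):
        stats = compute_marker_stats(small_ref)
        assert (stats["SecondFC"] >= 1.0).all()
        assert stats["frac_expressed_in_top"].between(0, 1).all()

    def test_single_type_errors(self, small_ref):
        import copy

        ref = copy.deepcopy(small_ref)
        ref.cell_type_labels = np.array(["T0"] * len(ref.cell_type_labels))
        with pytest.raises(ValueError, match="2 cell types"):
            compute_marker_stats(ref)


class TestSelectMarkers:
    def test_four_rules_applied(self, three_gene_stats):
        markers = select_markers(three_gene_stats, secondfc_min=1.5, min_frac_expressed=0.0)
        kept = sorted(g for genes in markers.values() for g in genes)
        assert kept == ["gA", "gC"]

    def test_degenerate_threshold_errors(self, three_gene_stats):
        with pytest.raises(ValueError, match="no markers"):
            select_markers(three_gene_stats, secondfc_min=np.inf, min_frac_expressed=0.0)

    def test_vacuous_thresholds_keep_all_unique_maxima(self, small_ref):
        stats = compute_marker_stats(small_ref)
        markers = select_markers(stats, logfc_min=0.0, logcpm_min=-np.inf,
                                 secondfc_min=1.0, min_frac_expressed=0.0)
        n_kept = sum(len(g) for g in markers.values())
        assert n_kept == len(stats)  # every gene has some top type

    def test_monotone_in_secondfc(self, small_ref):
        stats = compute_marker_stats(small_ref)
        sizes = []
        for t in (1.0, 1.5, 2.0, 3.0, 5.0):
            markers = select_markers(stats, secondfc_min=t, min_frac_expressed=0.0)
            sizes.append(sum(len(g) for g in markers.values()))
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_markers_recovered(self, small_ref):
        stats = compute_marker_stats(small_ref)
        markers = select_markers(stats, secondfc_min=1.5)
        recovered = 0
        total = 0
        for ct, planted in small_ref.planted_markers.items():
            total += len(planted)
            recovered += len(set(planted) & set(markers.get(ct, [])))
        assert recovered >= 0.9 * total


class TestBuildSignature:
    def test_mean_of_two_cells(self):
        from deconvkit.synthetic import SingleCellReference

        # two cells of type A with CPM 2 and 4 for gene g -> signature entry 3
        counts = np.array([[2, 999_998], [4, 999_996], [5, 999_995]], dtype=np.int64)
        ref = SingleCellReference(counts=counts,
                                  cell_type_labels=np.array(["A", "A", "B"]),
                                  gene_ids=["g", "__filler__"])
        sig = build_signature(ref, {"A": ["g"]})
        assert sig.values.loc["g", "A"] == pytest.approx(3.0)

    def test_one_cell_per_type_identity(self):
        ref = make_reference_from_cpm({"A": [10, 0], "B": [0, 10]}, ["g1", "g2"])
        sig = build_signature(ref, {"A": ["g1"], "B": ["g2"]})
        assert sig.values.loc["g1", "A"] == pytest.approx(10.0)
        assert sig.values.loc["g2", "B"] == pytest.approx(10.0)

    def test_planted_argmax_matches_type(self, small_ref, small_sig):
        for gene in small_sig.gene_ids:
            planted_type = next(
                (ct for ct, gs in small_ref.planted_markers.items() if gene in gs), None
            )
            if planted_type is not None:
                assert small_sig.values.loc[gene].idxmax() == planted_type

    def test_unknown_marker_named_in_error(self, small_ref):
        with pytest.raises(ValueError, match="nope"):
            build_signature(small_ref, {"T0": ["nope"]})


class TestAvgCelltypeCorrelation:
    def test_identical_columns(self):
        sig = make_signature(np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]]))
        assert avg_celltype_correlation(sig) == pytest.approx(1.0)

    def test_identity_columns_hand_value(self):
        sig = make_signature(np.eye(3))
        assert avg_celltype_correlation(sig) == pytest.approx(-0.5)

    def test_orthogonal_blocks_negative(self):
        X = np.zeros((6, 3))
        X[0:2, 0] = X[2:4, 1] = X[4:6, 2] = 5.0
        assert avg_celltype_correlation(make_signature(X)) < 0

    def test_constant_column_excluded(self):
        X = np.array([[1.0, 3.0, 2.0], [2.0, 3.0, 1.0]])
        sig = make_signature(X)
        # pairs with the constant column T1 are dropped; only (T0, T2) remains
        assert avg_celltype_correlation(sig) == pytest.approx(-1.0)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            avg_celltype_correlation(make_signature(np.ones((3, 3))))


class TestChooseSecondfcThreshold:
    def test_plateau_rule_on_stated_curve(self, monkeypatch):
        # avg corr [0.90, 0.60, 0.45, 0.44, 0.43] over [1, 1.5, 2, 2.5, 3] -> 2
        curve = dict(zip([1.0, 1.5, 2.0, 2.5, 3.0], [0.90, 0.60, 0.45, 0.44, 0.43]))
        import deconvkit.signature as sigmod

        monkeypatch.setattr(sigmod, "compute_marker_stats", lambda ref: None)
        monkeypatch.setattr(sigmod, "select_markers", lambda *a, **k: {"A": ["g"]})
        monkeypatch.setattr(sigmod, "build_signature",
                            lambda ref, m: types.SimpleNamespace(gene_ids=["g"]))
        calls = iter(sorted(curve))

        def fake_corr(sig):
            return curve[next(calls)]

        monkeypatch.setattr(sigmod, "avg_celltype_correlation", fake_corr)
        scan = sigmod.choose_secondfc_threshold(object(), list(curve), plateau_tol=0.05)
        assert scan.chosen_threshold == 2.0

    def test_flat_curve_chooses_first(self, monkeypatch):
        import deconvkit.signature as sigmod

        monkeypatch.setattr(sigmod, "compute_marker_stats", lambda ref: None)
        monkeypatch.setattr(sigmod, "select_markers", lambda *a, **k: {"A": ["g"]})
        monkeypatch.setattr(sigmod, "build_signature",
                            lambda ref, m: types.SimpleNamespace(gene_ids=["g"]))
        monkeypatch.setattr(sigmod, "avg_celltype_correlation", lambda sig: 0.5)
        scan = sigmod.choose_secondfc_threshold(object(), [1.0, 2.0, 3.0])
        assert scan.chosen_threshold == 1.0

    def test_steep_curve_falls_back_to_last(self, monkeypatch):
        import deconvkit.signature as sigmod

        vals = iter([0.9, 0.7, 0.5])
        monkeypatch.setattr(sigmod, "compute_marker_stats", lambda ref: None)
        monkeypatch.setattr(sigmod, "select_markers", lambda *a, **k: {"A": ["g"]})
        monkeypatch.setattr(sigmod, "build_signature",
                            lambda ref, m: types.SimpleNamespace(gene_ids=["g"]))
        monkeypatch.setattr(sigmod, "avg_celltype_correlation", lambda sig: next(vals))
        scan = sigmod.choose_secondfc_threshold(object(), [1.0, 2.0, 3.0])
        assert scan.chosen_threshold == 3.0

    def test_runs_on_generated_reference(self, small_ref):
        scan = choose_secondfc_threshold(small_ref, [1.0, 1.5, 2.0, 3.0, 5.0])
        assert scan.chosen_threshold in scan.thresholds
        assert all(-1 <= c <= 1 for c in scan.avg_correlation)

    def test_avg_correlation_nonincreasing_in_threshold(self, small_ref):
        scan = choose_secondfc_threshold(small_ref, [1.0, 1.5, 2.0, 3.0])
        diffs = np.diff(scan.avg_correlation)
        assert (diffs <= 1e-9).all()

    def test_too_few_candidates(self, small_ref):
        with pytest.raises(ValueError, match="3 candidate"):
            choose_secondfc_threshold(small_ref, [1.0, 2.0])


class TestSubsetTopFraction:
    def test_identity_at_fraction_one(self, small_sig):
        sub = subset_top_fraction(small_sig, 1.0)
        assert sub.gene_ids == small_sig.gene_ids

    def test_ceiling_rule(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10, 0, -1)
        X[:, 1] = 0.1
        sig = make_signature(X, logfc=np.arange(10, 0, -1, dtype=float))
        sub = subset_top_fraction(sig, 0.25)
        # all 10 markers belong to T0: ceil(0.25 * 10) = 3 kept
        assert len(sub.gene_ids) == 3

    def test_matches_exhaustive_sort_oracle(self, small_sig):
        frac = 0.5
        sub = subset_top_fraction(small_sig, frac)
        for ct, genes in small_sig.markers_by_type().items():
            expected = sorted(genes, key=lambda g: (-small_sig.logfc[g], g))
            expected = set(expected[: math.ceil(frac * len(genes))])
            got = set(sub.markers_by_type().get(ct, []))
            assert got == expected

    def test_invalid_fraction(self, small_sig):
        with pytest.raises(ValueError):
            subset_top_fraction(small_sig, 0.0)
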