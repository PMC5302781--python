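import numpy as np
import pandas as pd
import pytest

from spongenet import (
    EmptyResultError,
    IsoformTable,
    PairedProfile,
    SynthParams,
    abundance_shares,
    exon_usage_comparison,
    filter_isoforms,
    paired_ttest,
    pca,
    ratio_to_mirna,
    simulate_exon_counts,
    simulate_isoform_titration,
    titration_report,
    variation_matrix,
)
from spongenet.isoforms import annotate_sites, read_isoform_table, write_isoform_table
from spongenet.seeds import MiRNASeed


def make_table(normal, cancer, ids=None):
    ids = ids or [f"iso{i}" for i in range(len(normal))]
    patients = [f"p{i}" for i in range(len(normal[0]))]
    return IsoformTable(
        pd.DataFrame(normal, index=ids, columns=patients, dtype=float),
        pd.DataFrame(cancer, index=ids, columns=patients, dtype=float),
    )


class TestPairedTTest:
    def test_identical_profiles_give_p_one(self):
        assert paired_ttest([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_computed_value(self):
        # differences (1,2,3,4): t = 2.5 / (1.2910/2) ~ 3.873, p ~ 0.0305
        normal = [0.0, 0.0, 0.0, 0.0]
        cancer = [1.0, 2.0, 3.0, 4.0]
        assert paired_ttest(normal, cancer) == pytest.approx(0.0305, abs=0.001)

    def test_symmetric_under_condition_swap(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [2.0, 4.0, 4.0, 9.0]
        assert paired_ttest(a, b) == paired_ttest(b, a)

    def test_minimum_pairs_enforced(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])

    def test_unpaired_switch_differs_when_pairing_matters(self, rng):
        # a per-patient baseline makes the paired test far more powerful
        baseline = rng.normal(0, 5, size=30)
        normal = 10 + baseline + rng.normal(0, 0.2, 30)
        cancer = 10.5 + baseline + rng.normal(0, 0.2, 30)
        assert paired_ttest(normal, cancer) < 1e-6
        assert paired_ttest(normal, cancer, paired=False) > 0.05


class TestFilterIsoforms:
    def test_planted_shift_retained(self, rng):
        noise = rng.normal(0, 0.5, size=(2, 40))
        normal = np.vstack([10 + noise[0], 10 + noise[1]])
        cancer = np.vstack([13 + rng.normal(0, 0.5, 40), 10 + rng.normal(0, 0.5, 40)])
        out = filter_isoforms(make_table(normal, cancer))
        assert "iso0" in out.isoform_ids

    def test_type_one_error_controlled_under_permutation(self, rng):
        # permuting condition labels within patients keeps retention ~ alpha
        n = 72
        base_n = 10 * np.exp(rng.normal(0, 0.3, n))
        base_c = 10 * np.exp(rng.normal(0, 0.3, n))
        hits = 0
        reps = 200
        for _ in range(reps):
            swap = rng.random(n) < 0.5
            perm_n = np.where(swap, base_c, base_n)
            perm_c = np.where(swap, base_n, base_c)
            hits += paired_ttest(perm_n, perm_c) < 0.05
        # binomial slack: 3 sigma above alpha
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_alpha_zero_empties_table(self):
        table = make_table([[1, 2, 3]], [[4, 5, 6]])
        with pytest.raises(EmptyResultError):
            filter_isoforms(table, alpha=0.0)


class TestShares:
    def test_two_isoform_normalisation(self):
        table = make_table([[3, 3], [1, 1]], [[3, 3], [1, 1]])
        shares = abundance_shares(table, "normal")
        assert shares.tolist() == pytest.approx([75.0, 25.0])

    def test_single_isoform_is_everything(self):
        table = make_table([[2, 4]], [[2, 4]])
        assert abundance_shares(table, "cancer").tolist() == [100.0]

    def test_shares_sum_to_100_per_condition(self):
        ds = simulate_isoform_titration(SynthParams(random_seed=0))
        for cond in ("normal", "cancer"):
            assert abundance_shares(ds.table, cond).sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_total_undefined(self):
        table = make_table([[0, 0]], [[1, 1]])
        with pytest.raises(ValueError, match="zero"):
            abundance_shares(table, "normal")


class TestVariationMatrix:
    def test_identical_conditions_zero(self):
        table = make_table([[1, 2], [3, 4]], [[1, 2], [3, 4]])
        assert (variation_matrix(table).to_numpy() == 0).all()

    def test_direct_subtraction(self):
        table = make_table([[1, 2]], [[3, 2]])
        assert variation_matrix(table).iloc[0].tolist() == [2.0, 0.0]

    def test_antisymmetric_under_condition_swap(self):
        ds = simulate_isoform_titration(SynthParams(random_seed=1))
        swapped = IsoformTable(ds.table.cancer, ds.table.normal)
        a = variation_matrix(ds.table).to_numpy()
        b = variation_matrix(swapped).to_numpy()
        assert np.allclose(a, -b)

    def test_unpaired_patient_rejected(self):
        normal = pd.DataFrame([[1.0, 2.0]], index=["i"], columns=["p1", "p2"])
        cancer = pd.DataFrame([[1.0, 2.0]], index=["i"], columns=["p1", "p3"])
        with pytest.raises(ValueError, match="unpaired"):
            IsoformTable(normal, cancer)


class TestPCA:
    def test_rank_one_data(self):
        data = np.outer([1.0, 2.0, 4.0], [1.0, -2.0, 0.5])
        res = pca(data)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance_ratio[1:] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_eigenvalues(self):
        # rows (2,0), (0,0), (-2,0): centered column variance (4+0+4)/2 = 4
        res = pca(np.array([[2.0, 0.0], [0.0, 0.0], [-2.0, 0.0]]))
        assert res.eigenvalues == pytest.approx([4.0, 0.0], abs=1e-12)
        assert res.explained_variance_ratio == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_reconstruction_identity(self, rng):
        data = pd.DataFrame(rng.normal(size=(8, 5)))
        res = pca(data)
        centered = data.to_numpy() - data.to_numpy().mean(axis=0)
        assert np.allclose(
            centered, res.scores.to_numpy() @ res.factors.to_numpy().T, atol=1e-9
        )

    def test_factors_orthonormal_and_fractions_valid(self, rng):
        res = pca(rng.normal(size=(10, 6)))
        f = res.factors.to_numpy()
        assert np.allclose(f.T @ f, np.eye(f.shape[1]), atol=1e-9)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_matches_sklearn(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        data = rng.normal(size=(12, 7))
        res = pca(data)
        ref = sklearn_pca(n_components=7).fit(data)
        assert np.allclose(res.eigenvalues, ref.explained_variance_, atol=1e-9)
        assert np.allclose(
            np.abs(res.factors.to_numpy()), np.abs(ref.components_.T), atol=1e-9
        )

    def test_constant_data_signalled(self):
        with pytest.raises(ValueError, match="no variation"):
            pca(np.ones((4, 3)))


class TestRatioToMirna:
    def _table_and_profile(self):
        table = make_table([[10.0, 10.0, 10.0, 10.0]], [[10.0, 10.0, 10.0, 10.0]])
        mirna = PairedProfile(
            pd.Series(5.0, index=table.patient_ids),
            pd.Series(5.0, index=table.patient_ids),
        )
        return table, mirna

    def test_mean_ratio(self):
        table, mirna = self._table_and_profile()
        assert ratio_to_mirna(table, "iso0", mirna, "normal").ratio == pytest.approx(2.0)

    def test_scale_invariance(self):
        table, mirna = self._table_and_profile()
        scaled = IsoformTable(table.normal * 7, table.cancer * 7)
        scaled_mirna = PairedProfile(mirna.normal * 7, mirna.cancer * 7)
        a = ratio_to_mirna(table, "iso0", mirna, "normal").ratio
        b = ratio_to_mirna(scaled, "iso0", scaled_mirna, "normal").ratio
        assert a == pytest.approx(b)

    def test_zero_mirna_mean_undefined(self):
        table, mirna = self._table_and_profile()
        zero = PairedProfile(mirna.normal * 0, mirna.cancer)
        with pytest.raises(ValueError, match="not positive"):
            ratio_to_mirna(table, "iso0", zero, "normal")

    def test_site_isoform_ratio_falls_in_cancer(self):
        # the planted titration structure: site isoform +30%, miRNA 4-8x up
        drops = []
        for seed in range(20):
            ds = simulate_isoform_titration(SynthParams(random_seed=seed))
            rn = ratio_to_mirna(ds.table, "iso-site", ds.mirna, "normal")
            rc = ratio_to_mirna(ds.table, "iso-site", ds.mirna, "cancer")
            drops.append(rc.ratio < rn.ratio)
        assert all(drops)

    def test_matched_fold_isoform_shows_no_drop(self):
        # when the no-site isoform's fold matches the miRNA's, its ratio holds
        params = SynthParams(random_seed=2, mirna_fold_range=(4.0, 4.0))
        ds = simulate_isoform_titration(params)
        fold = ds.truth["dominant_fold"]
        scaled_mirna = PairedProfile(
            ds.mirna.normal, ds.mirna.cancer * (fold / ds.truth["mirna_fold"])
        )
        rn = ratio_to_mirna(ds.table, "iso-dom", scaled_mirna, "normal")
        rc = ratio_to_mirna(ds.table, "iso-dom", scaled_mirna, "cancer")
        assert rc.ratio == pytest.approx(rn.ratio, rel=0.15)
        assert rc.p_vs_other_condition > 0.05


class TestExonUsage:
    def test_identical_conditions_fold_one(self):
        ds = simulate_exon_counts(SynthParams(random_seed=0, exon_fold=1.0))
        cmp = exon_usage_comparison(ds.counts, ds.samples)
        assert not cmp["upregulated"].any()
        assert ds.truth["upregulated_exons"] == []

    def test_breakpoint_at_last_exon_flags_nothing(self):
        params = SynthParams(random_seed=0, n_exons=6, exon_breakpoint=5)
        ds = simulate_exon_counts(params)
        assert ds.truth["upregulated_exons"] == ["exon6"]
        params_none = SynthParams(random_seed=0, n_exons=6, exon_breakpoint=5,
                                  exon_fold=1.0)
        assert simulate_exon_counts(params_none).truth["upregulated_exons"] == []

    def test_planted_exons_flagged(self):
        ok = 0
        for seed in range(20):
            ds = simulate_exon_counts(SynthParams(random_seed=seed))
            cmp = exon_usage_comparison(ds.counts, ds.samples)
            ok += set(cmp.index[cmp["upregulated"]]) == set(ds.truth["upregulated_exons"])
        assert ok >= 19

    def test_zero_normal_mean_flagged_undefined(self):
        counts = pd.DataFrame(
            [[0.0, 0.0, 5.0, 6.0]], index=["exon1"],
            columns=["p1-N", "p2-N", "p1-C", "p2-C"],
        )
        samples = pd.DataFrame(
            {"patient_id": ["p1", "p2", "p1", "p2"],
             "condition": ["normal", "normal", "cancer", "cancer"]},
            index=counts.columns,
        )
        cmp = exon_usage_comparison(counts, samples)
        assert cmp.loc["exon1", "fold_undefined"]
        assert not cmp.loc["exon1", "upregulated"]


class TestTableIO:
    def test_round_trip(self, tmp_path):
        ds = simulate_isoform_titration(SynthParams(random_seed=3))
        write_isoform_table(ds.table, tmp_path / "n.tsv", tmp_path / "c.tsv")
        back = read_isoform_table(tmp_path / "n.tsv", tmp_path / "c.tsv")
        assert np.allclose(back.normal.to_numpy(), ds.table.normal.to_numpy())
        assert back.isoform_ids == ds.table.isoform_ids

    def test_annotate_sites_from_sequences(self):
        table = make_table([[1, 1], [1, 1]], [[1, 1], [1, 1]], ids=["a", "b"])
        seeds = [MiRNASeed("miR-200b", "UAAUACUGCCUGGUAAUGAUGA")]
        annotate_sites(table, {"a": "CCAGTATTCC", "b": "CCCCCCCCCC"}, seeds)
        assert table.site_annotations["a"] == {"miR-200b"}
        assert table.site_annotations["b"] == set()

    def test_titration_report_fields(self):
        ds = simulate_isoform_titration(SynthParams(random_seed=4))
        report = titration_report(ds.table, ds.mirna, ds.mirna_id)
        assert report["share_normal_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        site = report.loc["iso-site"]
        assert site["ratio_to_miR-ref_cancer"] < site["ratio_to_miR-ref_normal"]
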