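"""Copy-number features, gene selection, Naïve Bayes predictor, CV."""

import numpy as np
import pandas as pd
import pytest

from ecsubtype.cn import (
    CnFeaturizer, CNCluster4Classifier, Cluster4Model, canonicalize_segments,
    cross_validate, extract_cn_features, feature_row, select_top_genes,
    train_cluster4_model,
)
from ecsubtype.genes import synthetic_gene_model

GM = synthetic_gene_model()


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number"])


class TestFeatureExtraction:
    def test_diploid_genome(self):
        seg = seg_frame([("chr1", 0, 60_000_000, 2.0)])
        fv = extract_cn_features(seg, GM, ["GENE01"])
        assert fv.n_gains == fv.n_losses == 0
        assert fv.ploidy == pytest.approx(2.0)
        assert fv.altered_mb == 0.0

    def test_single_gain_over_selected_gene(self):
        # GENE01 sits at chr1:5,000,000-5,100,000
        seg = seg_frame([
            ("chr1", 0, 4_000_000, 2.0),
            ("chr1", 4_000_000, 7_000_000, 4.0),  # 3 Mb gain overlapping GENE01
            ("chr1", 7_000_000, 60_000_000, 2.0),
        ])
        fv = extract_cn_features(seg, GM, ["GENE01", "GENE02"])
        assert fv.n_gains == 1 and fv.n_losses == 0
        assert fv.gains_per_chrom["chr1"] == 1
        assert fv.gene_alteration_counts == {"GENE01": 1, "GENE02": 0}
        assert fv.altered_mb == pytest.approx(3.0)
        expected_ploidy = (4e6 * 2 + 3e6 * 4 + 53e6 * 2) / 60e6
        assert fv.ploidy == pytest.approx(expected_ploidy)

    def test_empty_segments_default_quiet(self):
        with pytest.warns(UserWarning):
            fv = extract_cn_features(seg_frame([]), GM, ["GENE01"])
        assert fv.ploidy == 2.0 and fv.n_gains == 0

    def test_split_and_order_invariance(self):
        base = seg_frame([
            ("chr2", 0, 10_000_000, 3.2),
            ("chr2", 10_000_000, 60_000_000, 2.0),
        ])
        split = seg_frame([
            ("chr2", 10_000_000, 60_000_000, 2.0),
            ("chr2", 4_000_000, 10_000_000, 3.2),
            ("chr2", 0, 4_000_000, 3.2),
        ])
        genes = ["GENE02"]
        a = feature_row(extract_cn_features(base, GM, genes), genes)
        b = feature_row(extract_cn_features(split, GM, genes), genes)
        pd.testing.assert_series_equal(a, b)

    def test_overlapping_segments_rejected(self):
        bad = seg_frame([("chr1", 0, 10, 2.0), ("chr1", 5, 20, 3.0)])
        with pytest.raises(ValueError, match="overlap"):
            canonicalize_segments(bad)

    def test_per_chrom_counts_sum_to_totals(self):
        seg = seg_frame([
            ("chr1", 0, 5_000_000, 4.0), ("chr1", 5_000_000, 60_000_000, 2.0),
            ("chr5", 0, 2_000_000, 1.0), ("chr5", 2_000_000, 60_000_000, 2.0),
        ])
        fv = extract_cn_features(seg, GM, [])
        assert sum(fv.gains_per_chrom.values()) == fv.n_gains == 1
        assert sum(fv.losses_per_chrom.values()) == fv.n_losses == 1


class TestGeneSelection:
    def test_exactly_k_altered_genes_selected(self):
        inc = pd.DataFrame(0, index=range(10), columns=[f"G{i:02d}" for i in range(30)])
        for i, g in enumerate(inc.columns[:25]):
            inc.loc[: min(i, 9), g] = 1
        assert set(select_top_genes(inc, k=25)) == set(inc.columns[:25])

    def test_tie_broken_lexicographically(self):
        inc = pd.DataFrame({"B": [1, 1], "A": [1, 1], "C": [1, 0]})
        assert select_top_genes(inc, k=2) == ["A", "B"]

    def test_padding_warns_and_is_deterministic(self):
        inc = pd.DataFrame({"Z": [1, 1], "A": [0, 0], "B": [0, 0]})
        with pytest.warns(UserWarning):
            got = select_top_genes(inc, k=3)
        assert got == ["Z", "A", "B"]


class TestNaiveBayes:
    def test_closed_form_posterior_with_unequal_priors(self):
        # class 0: mean 0, var 1, prior 0.74; class 1: mean 2, var 1, prior 0.26
        X = np.array([[-1.0], [1.0]] * 37 + [[1.0], [3.0]] * 13)
        y = np.array([0] * 74 + [1] * 26)
        clf = CNCluster4Classifier().fit(X, y)
        post = clf.posterior_cluster4([[1.0]])[0]
        assert post == pytest.approx(0.26, abs=1e-6)

    def test_symmetric_case_posterior_half(self):
        X = np.array([[-2.0], [0.0], [0.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        clf = CNCluster4Classifier().fit(X, y)
        assert clf.posterior_cluster4([[0.0]])[0] == pytest.approx(0.5, abs=1e-6)

    def test_separable_training_accuracy(self):
        X = np.array([[100.0]] * 10 + [[0.0]] * 10) + np.arange(20).reshape(-1, 1) * 0.01
        y = np.array([1] * 10 + [0] * 10)
        clf = CNCluster4Classifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_single_class_refused(self):
        with pytest.raises(ValueError, match="single class"):
            CNCluster4Classifier().fit(np.zeros((4, 2)), np.zeros(4))

    def test_posterior_sums_to_one_and_flag_matches_argmax(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(2, 1, (30, 3))])
        y = np.r_[np.zeros(30), np.ones(30)]
        clf = CNCluster4Classifier().fit(X, y)
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (clf.predict(X) == proba.argmax(axis=1)).all()


class TestModelRoundTrip:
    def test_json_save_load_preserves_posteriors(self, tmp_path, cn_model):
        path = tmp_path / "model.json"
        cn_model.save(path)
        loaded = Cluster4Model.load(path)
        seg = seg_frame([("chr1", 0, 60_000_000, 2.0)])
        f1, p1 = cn_model.predict_sample(seg)
        f2, p2 = loaded.predict_sample(seg)
        assert f1 == f2 and p1 == pytest.approx(p2, rel=1e-12)
        assert loaded.featurizer.selected_genes_ == cn_model.featurizer.selected_genes_


class TestCrossValidation:
    def _separable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (74, 2)), rng.normal(10, 0.5, (26, 2))])
        y = np.r_[np.zeros(74), np.ones(26)]
        return X, y

    def test_perfectly_separable_scores_one(self):
        X, y = self._separable()
        m = cross_validate(X, y, folds=5, seed=0)
        assert (m.accuracy, m.precision, m.recall, m.f1, m.roc_auc) == (1, 1, 1, 1, 1)

    def test_deterministic_for_fixed_seed(self):
        X, y = self._separable()
        X = X + np.random.default_rng(1).normal(0, 3, X.shape)  # make folds matter
        a = cross_validate(X, y, folds=5, seed=7)
        b = cross_validate(X, y, folds=5, seed=7)
        assert a == b
        for v in (a.accuracy, a.precision, a.recall, a.f1, a.roc_auc):
            assert 0.0 <= v <= 1.0

    def test_requires_enough_members_per_class(self):
        X = np.zeros((6, 1))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            cross_validate(X, y, folds=5, seed=0)


class TestFeaturizer:
    def test_learns_gene_selection_and_fixed_layout(self):
        rows = []
        for sid, cn in (("s1", 4.0), ("s2", 4.0), ("s3", 2.0)):
            rows.append((sid, "chr1", 4_900_000, 5_200_000, cn))  # over GENE01
            rows.append((sid, "chr1", 5_200_000, 60_000_000, 2.0))
        seg = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                          "copy_number"])
        fz = CnFeaturizer(n_genes=3).fit(seg)
        assert fz.selected_genes_[0] == "GENE01"
        X = fz.transform(seg)
        assert list(X.index) == ["s1", "s2", "s3"]
        assert X.loc["s1", "alt_GENE01"] == 1 and X.loc["s3", "alt_GENE01"] == 0
        # 2 totals + 23 gains + 23 losses + 3 genes + ploidy + altered_mb
        assert X.shape[1] == 2 + 23 + 23 + 3 + 2
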