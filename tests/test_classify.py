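"""Weighted metrics vs straight-line oracle, PCA reduction, and the protocol."""

import numpy as np
import pytest

import genetexture as gt
from genetexture.classify import confusion_counts, dataset_from_frame

from conftest import random_sequence


def straight_line_metrics(conf: np.ndarray):
    """Independent evaluation of the weighted one-vs-rest metric formulas.

    ``conf[i, j]`` = samples of true class i predicted as class j.
    """
    C = conf.shape[0]
    n = conf.sum(axis=1)
    total = conf.sum()
    acc = prec = rec = f1 = 0.0
    for i in range(C):
        tp = conf[i, i]
        fn = n[i] - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        p_i = tp / (tp + fp) if tp + fp > 0 else 0.0
        r_i = tp / (tp + fn) if tp + fn > 0 else 0.0
        f_i = 2 * p_i * r_i / (p_i + r_i) if p_i + r_i > 0 else 0.0
        acc += n[i] * (tp + tn) / total
        prec += n[i] * p_i
        rec += n[i] * r_i
        f1 += n[i] * f_i
    w = n.sum()
    return tuple(100 * x / w for x in (acc, prec, rec, f1))


def counts_from_confusion(conf: np.ndarray):
    C = conf.shape[0]
    total = int(conf.sum())
    out = []
    for i in range(C):
        tp = int(conf[i, i])
        fn = int(conf[i].sum() - tp)
        fp = int(conf[:, i].sum() - tp)
        tn = total - tp - fn - fp
        out.append((tp, tn, fp, fn, tp + fn))
    return out


class TestWeightedMetrics:
    def test_perfect_prediction_is_100(self):
        conf = np.diag([7, 5])
        assert gt.weighted_metrics(counts_from_confusion(conf)) == (100.0,) * 4

    def test_three_class_example_matches_oracle(self):
        conf = np.array([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        got = gt.weighted_metrics(counts_from_confusion(conf))
        expected = straight_line_metrics(conf)
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-10)

    def test_random_confusions_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            C = int(rng.integers(2, 6))
            conf = rng.integers(0, 20, size=(C, C))
            if conf.sum(axis=1).min() == 0:
                continue
            got = gt.weighted_metrics(counts_from_confusion(conf))
            np.testing.assert_allclose(got, straight_line_metrics(conf), atol=1e-10)
            assert all(0 <= m <= 100 for m in got)

    def test_ovr_accuracy_dominates_plain_accuracy(self):
        # the TN term makes one-vs-rest accuracy >= plain multiclass accuracy
        rng = np.random.default_rng(19)
        for _ in range(1000):
            C = int(rng.integers(2, 6))
            conf = rng.integers(0, 20, size=(C, C))
            if conf.sum(axis=1).min() == 0:
                continue
            acc = gt.weighted_metrics(counts_from_confusion(conf))[0]
            plain = 100 * np.trace(conf) / conf.sum()
            assert acc >= plain - 1e-9

    def test_weighted_recall_equals_plain_accuracy(self):
        rng = np.random.default_rng(23)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        counts = confusion_counts(y_true, y_pred)
        rec = gt.weighted_metrics(counts)[2]
        assert rec == pytest.approx(100 * np.mean(y_true == y_pred), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gt.weighted_metrics([(1, 2, -1, 0, 1)])


class TestAssembleFeatures:
    def _seqs(self, n, rng, length=60):
        return [random_sequence(rng, length, rec_id=f"s{i}") for i in range(n)]

    def test_forty_columns_without_classic(self):
        rng = np.random.default_rng(0)
        data = gt.assemble_features(self._seqs(10, rng), ["a"] * 5 + ["b"] * 5)
        assert data.matrix.shape == (10, 40)
        assert data.names[:2] == ["f1", "f2"]

    def test_forty_four_columns_with_classic(self):
        rng = np.random.default_rng(1)
        data = gt.assemble_features(
            self._seqs(10, rng), ["a"] * 5 + ["b"] * 5,
            include_classic=True, fd_cap=64,
        )
        assert data.matrix.shape == (10, 44)
        assert data.names[-4:] == ["SE", "HE", "MSE", "FD"]
        assert not np.isnan(data.matrix).any()

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="2 classes"):
            gt.assemble_features(self._seqs(4, rng), ["a"] * 4)

    def test_hurst_failure_imputed_with_column_mean(self):
        rng = np.random.default_rng(3)
        seqs = self._seqs(4, rng) + [gt.NucleotideSequence("const", "A" * 60)]
        data = gt.assemble_features(
            seqs, ["a", "a", "b", "b", "b"], include_classic=True, fd_cap=64
        )
        he_col = data.names.index("HE")
        ok = [
            gt.hurst_exponent(gt.encode_binary(s)) for s in seqs[:4]
        ]
        assert data.matrix[4, he_col] == pytest.approx(np.mean(ok))


class TestPCAReduce:
    def _toy(self, rng, n=60, d=10):
        X = rng.normal(size=(n, d)) * np.linspace(5, 0.1, d)
        y = np.array(["a", "b"] * (n // 2))
        names = [f"x{i}" for i in range(d)]
        return gt.LabeledDataset(X[: n // 2], y[: n // 2], names), gt.LabeledDataset(
            X[n // 2 :], y[n // 2 :], names
        )

    def test_dimension_monotone_in_variation(self):
        rng = np.random.default_rng(29)
        train, test = self._toy(rng)
        dims = [
            gt.pca_reduce(train, test, v)[2] for v in (0.85, 0.9, 0.95, 0.99)
        ]
        assert dims == sorted(dims)

    def test_full_variation_keeps_rank(self):
        rng = np.random.default_rng(30)
        train, test = self._toy(rng, n=40, d=6)
        _, _, d, eig = gt.pca_reduce(train, test, 1.0)
        assert d == np.linalg.matrix_rank((train.matrix - train.matrix.mean(0)) / train.matrix.std(0))
        assert (np.diff(eig) <= 1e-9).all()  # eigenvalues descending

    def test_constant_column_carries_no_variance(self):
        rng = np.random.default_rng(31)
        X = np.column_stack([rng.normal(size=30), np.full(30, 7.0)])
        y = np.array(["a", "b"] * 15)
        train = gt.LabeledDataset(X[:20], y[:20], ["x0", "x1"])
        test = gt.LabeledDataset(X[20:], y[20:], ["x0", "x1"])
        _, _, d, _ = gt.pca_reduce(train, test, 0.99)
        assert d == 1

    def test_invalid_variation_rejected(self):
        rng = np.random.default_rng(32)
        train, test = self._toy(rng)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                gt.pca_reduce(train, test, bad)


class TestEvaluateProtocol:
    def _gaussian_toy(self, rng, sep=10.0, n=40):
        X = np.vstack([
            rng.normal(0, 1, size=(n, 4)),
            rng.normal(sep, 1, size=(n, 4)),
        ])
        y = np.array(["a"] * n + ["b"] * n)
        return gt.LabeledDataset(X, y, [f"x{i}" for i in range(4)])

    @pytest.mark.parametrize("clf", ["knn", "dt", "svm"])
    def test_separable_classes_score_100(self, clf):
        rng = np.random.default_rng(37)
        rep = gt.evaluate_protocol(self._gaussian_toy(rng), classifier=clf, seed=0)
        assert rep.f1 == pytest.approx(100.0)

    @pytest.mark.parametrize("protocol", ["repeated-split", "cv5"])
    def test_deterministic_given_seed(self, protocol):
        rng = np.random.default_rng(41)
        data = self._gaussian_toy(rng, sep=1.0)
        r1 = gt.evaluate_protocol(data, "knn", protocol, seed=7)
        r2 = gt.evaluate_protocol(data, "knn", protocol, seed=7)
        assert r1.to_dict() == r2.to_dict()
        assert r1.protocol == protocol and r1.n_splits == 5

    def test_singleton_class_rejected(self):
        X = np.zeros((3, 2))
        data = gt.LabeledDataset(X, np.array(["a", "a", "b"]), ["x0", "x1"])
        with pytest.raises(ValueError, match="'b'"):
            gt.evaluate_protocol(data, "knn")

    def test_report_round_trips_through_frame(self, tmp_path):
        rng = np.random.default_rng(43)
        data = self._gaussian_toy(rng)
        records = list(zip([f"s{i}" for i in range(80)], data.labels, data.matrix))
        path = tmp_path / "f.csv"
        gt.write_feature_table(records, path)
        back = dataset_from_frame(gt.read_feature_table(path))
        np.testing.assert_allclose(back.matrix, data.matrix, atol=1e-12)
        assert (back.labels == data.labels).all()
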