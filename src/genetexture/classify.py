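"""Feature assembly, PCA reduction, classification protocol and weighted metrics.

The evaluation convention is one-vs-rest per class on a single multiclass
prediction, with every metric weighted by the class sizes n_i. Note the
accuracy definition: each class's one-vs-rest accuracy includes its true
negatives, so the weighted accuracy is generally higher than plain multiclass
accuracy — this nonstandard form is kept deliberately, alongside weighted
precision, recall and F1, because the species sets it was designed for are
imbalanced.

The split protocol offers two modes. ``repeated-split`` (default) runs five
repetitions of a stratified 50/50 train/test split and averages the test
metrics; ``cv5`` is plain stratified five-fold cross-validation. In both, the
z-score scaler and any PCA are fit on the training half only and applied to
the test half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import classic
from .cooc import cooc_feature_vector
from .seqio import NucleotideSequence, encode_binary, feature_names

logger = logging.getLogger("genetexture")

ClassifierName = Literal["knn", "dt", "svm"]
ProtocolName = Literal["repeated-split", "cv5"]


@dataclass
class LabeledDataset:
    """An n_samples x dimension feature matrix with class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    names: list[str]
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels/matrix row mismatch")
        if np.isnan(self.matrix).any():
            raise ValueError("matrix contains missing values after imputation")

    @property
    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {str(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class EvalReport:
    """Averaged weighted metrics (percent) plus protocol metadata."""

    classifier: str
    protocol: str
    seed: int
    n_splits: int
    scaling: bool
    pca_variation: float | None
    pca_dimension: int | None
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def assemble_features(
    seqs: Sequence[NucleotideSequence],
    labels: Sequence[str],
    include_classic: bool = False,
    mse_mode: classic.MSEMode = "window",
    fd_cap: int = classic.DEFAULT_FD_CAP,
) -> LabeledDataset:
    """Build the 40-column (or 44-column with SE/HE/MSE/FD) labeled matrix.

    Hurst-exponent failures (constant or too-short binary encodings) are
    imputed with the column mean over the successful rows and logged; a
    column with no successful value at all is an error. At least two classes
    are required.
    """
    if len(seqs) != len(labels):
        raise ValueError("one label per sequence required")
    if len(set(labels)) < 2:
        raise ValueError("at least 2 classes required for classification")
    rows = []
    for s in seqs:
        vec = cooc_feature_vector(s)
        if include_classic:
            b = encode_binary(s)
            try:
                he = classic.hurst_exponent(b)
            except ValueError as exc:
                logger.warning("HE failed for %r (%s); will impute", s.id, exc)
                he = np.nan
            extra = np.array(
                [
                    classic.shannon_entropy(b),
                    he,
                    classic.modified_shannon_entropy(b, mode=mse_mode),
                    classic.fractal_dimension(s, cap=fd_cap),
                ]
            )
            vec = np.concatenate([vec, extra])
        rows.append(vec)
    mat = np.vstack(rows)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        bad = np.isnan(col)
        if bad.all():
            raise ValueError(f"feature column {j} failed for every sequence")
        if bad.any():
            col[bad] = col[~bad].mean()
    return LabeledDataset(
        matrix=mat,
        labels=np.asarray(labels),
        names=feature_names(mat.shape[1]),
        ids=[s.id for s in seqs],
    )


# ---------------------------------------------------------------------------
# Weighted one-vs-rest metrics


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence | None = None
) -> list[tuple[int, int, int, int, int]]:
    """Per-class one-vs-rest (TP, TN, FP, FN, n) from a multiclass prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    out = []
    total = y_true.size
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        tn = total - tp - fp - fn
        out.append((tp, tn, fp, fn, tp + fn))
    return out


def weighted_metrics(
    per_class_counts: Sequence[tuple[int, int, int, int, int]],
) -> tuple[float, float, float, float]:
    """Class-size-weighted accuracy, precision, recall and F1, in percent.

    Each class contributes its one-vs-rest counts (TP, TN, FP, FN, n); the
    accuracy term includes TN, precision with TP + FP = 0 is defined as 0,
    and an F1 term with zero precision and recall is 0.
    """
    w_n = 0
    acc = prec = rec = f1 = 0.0
    for tp, tn, fp, fn, n in per_class_counts:
        if min(tp, tn, fp, fn, n) < 0:
            raise ValueError("negative confusion counts")
        w_n += n
        denom = tp + tn + fp + fn
        acc += n * ((tp + tn) / denom if denom else 0.0)
        p_i = tp / (tp + fp) if (tp + fp) else 0.0
        r_i = tp / (tp + fn) if (tp + fn) else 0.0
        prec += n * p_i
        rec += n * r_i
        f1 += n * (2 * p_i * r_i / (p_i + r_i) if (p_i + r_i) else 0.0)
    if w_n == 0:
        raise ValueError("empty class counts")
    return tuple(100.0 * x / w_n for x in (acc, prec, rec, f1))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Scaling and PCA


def _fit_scaler(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and guarded stds (zero-variance columns map to 0)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant column -> centered to exactly 0
    return mu, sd


def pca_reduce(
    train: LabeledDataset,
    test: LabeledDataset,
    variation: float,
) -> tuple[LabeledDataset, LabeledDataset, int, np.ndarray]:
    """Project both sets onto the leading principal components of the train set.

    Columns are z-scored with train-set parameters first (zero-variance guard:
    constant columns become exactly 0). The retained dimension d is the
    smallest number of components whose cumulative explained-variance ratio
    reaches ``variation``; eigenvalues are returned in descending order.
    """
    if not (0.0 < variation <= 1.0):
        raise ValueError(f"variation must be in (0, 1], got {variation}")
    mu, sd = _fit_scaler(train.matrix)
    Xtr = (train.matrix - mu) / sd
    Xte = (test.matrix - mu) / sd
    pca = PCA(n_components=min(Xtr.shape), svd_solver="full")
    pca.fit(Xtr)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    # rank-deficient matrices carry trailing zero components; keep the span
    d = int(np.searchsorted(cum, variation - 1e-12) + 1)
    d = min(d, int(np.sum(pca.explained_variance_ > 1e-12)) or 1)
    Ttr = pca.transform(Xtr)[:, :d]
    Tte = pca.transform(Xte)[:, :d]
    names = [f"pc{i+1}" for i in range(d)]
    return (
        LabeledDataset(Ttr, train.labels, names, train.ids),
        LabeledDataset(Tte, test.labels, names, test.ids),
        d,
        pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# Protocol


def make_classifier(name: ClassifierName, seed: int):
    """Default classifiers: KNN k=5 Euclidean; DT Gini; SVM RBF C=1."""
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, decision_function_shape="ovr",
                   random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def evaluate_protocol(
    data: LabeledDataset,
    classifier: ClassifierName = "svm",
    protocol: ProtocolName = "repeated-split",
    seed: int = 0,
    scaling: bool = True,
    pca_variation: float | None = None,
) -> EvalReport:
    """Train and score a classifier under the stratified split protocol.

    ``repeated-split``: 5 repetitions of a stratified 50/50 split; ``cv5``:
    stratified five-fold cross-validation. Per split, the scaler and any PCA
    are fit on the training part only. Reported metrics are means over
    splits, deterministic given ``seed``.
    """
    y = data.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("at least 2 classes required")
    for c, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {c!r} has a single sample")
    if protocol == "repeated-split":
        splitter = StratifiedShuffleSplit(
            n_splits=5, train_size=0.5, test_size=0.5, random_state=seed
        )
    elif protocol == "cv5":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    metrics = np.zeros(4)
    agg: dict[str, np.ndarray] = {str(c): np.zeros(5) for c in classes}
    dims: list[int] = []
    n_splits = 0
    for train_idx, test_idx in splitter.split(data.matrix, y):
        Xtr, Xte = data.matrix[train_idx], data.matrix[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        if scaling or pca_variation is not None:
            mu, sd = _fit_scaler(Xtr)
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        if pca_variation is not None:
            tr = LabeledDataset(Xtr, ytr, [f"x{i}" for i in range(Xtr.shape[1])])
            te = LabeledDataset(Xte, yte, tr.names)
            tr, te, d, _ = pca_reduce(tr, te, pca_variation)
            Xtr, Xte = tr.matrix, te.matrix
            dims.append(d)
        clf = make_classifier(classifier, seed)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        pc = confusion_counts(yte, pred, classes)
        metrics += np.array(weighted_metrics(pc))
        for c, counts_c in zip(classes, pc):
            agg[str(c)] += np.array(counts_c)
        n_splits += 1
    metrics /= n_splits
    per_class = {
        c: dict(zip(("TP", "TN", "FP", "FN", "n"), (v / n_splits).tolist()))
        for c, v in agg.items()
    }
    return EvalReport(
        classifier=classifier,
        protocol=protocol,
        seed=seed,
        n_splits=n_splits,
        scaling=scaling,
        pca_variation=pca_variation,
        pca_dimension=int(round(np.mean(dims))) if dims else None,
        accuracy=float(metrics[0]),
        precision=float(metrics[1]),
        recall=float(metrics[2]),
        f1=float(metrics[3]),
        per_class=per_class,
    )


def dataset_from_frame(df: pd.DataFrame) -> LabeledDataset:
    """Build a dataset from a feature table (id, label, features...)."""
    feats = df.drop(columns=["id", "label"])
    return LabeledDataset(
        matrix=feats.to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
        names=list(feats.columns),
        ids=list(df["id"]),
    )
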