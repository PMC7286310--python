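"""Classification, biomarker extraction and link-wise testing on connectivity.

Each fMRI-like session yields one sample whose features are the vectorized
connectivity links (EC over the structural mask, FC upper triangle, or flow
entries); labels are the cognitive condition or the subject identity.
Cross-validation is group-aware: when predicting the condition, all sessions
of a subject fall on the same side of every split, since paired sessions of
one subject are far more similar than chance and would inflate accuracy.

Recursive feature elimination (RFE) with a multinomial logistic regression
ranks links by importance and defines a support network (biomarker) at the
accuracy maximum.  Link-wise Mann-Whitney tests with Bonferroni and
Benjamini-Hochberg corrections provide the mass-univariate comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, silhouette_score
from sklearn.model_selection import GroupShuffleSplit, LeaveOneGroupOut
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mouec")


@dataclass
class CohortSample:
    """One session's feature vector with its subject and condition labels."""

    features: np.ndarray
    subject_id: str
    condition: str
    session_id: str = ""
    feature_index: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class ClassificationResult:
    accuracies: np.ndarray
    mean_accuracy: float
    chance_level: float
    confusion: np.ndarray  # true x predicted counts summed over splits
    classes: list[str]
    classifier_name: str
    scheme_name: str
    n_splits: int
    seed: int


@dataclass
class BiomarkerRanking:
    """RFE output: per-feature rank (1 = most informative) and support set."""

    rank: np.ndarray
    support: np.ndarray
    accuracy_curve: list[tuple[int, float]]  # (n features retained, CV accuracy)


@dataclass
class LinkTestResult:
    p_values: np.ndarray
    bonferroni_threshold: float
    bh_rejections: np.ndarray
    n_pairs_tested: int
    test_name: str = "mannwhitneyu"


# ---------------------------------------------------------------------------
# feature vectorization


def vectorize_connectivity(
    matrix: np.ndarray, mask_or_mode
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Vectorize a connectivity matrix into a feature vector plus index.

    With a boolean/0-1 mask the masked entries are taken in row-major order
    (EC mode); with the string ``"fc"`` the strict upper triangle is taken
    (symmetric FC mode).  The returned index maps each feature back to its
    (source ROI, target ROI) pair.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    if isinstance(mask_or_mode, str):
        if mask_or_mode != "fc":
            raise ValueError(f"unknown vectorization mode {mask_or_mode!r}")
        idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        mask = np.asarray(getattr(mask_or_mode, "mask", mask_or_mode)).astype(bool)
        if mask.shape != matrix.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match matrix shape {matrix.shape}"
            )
        idx = [(i, j) for i in range(n) for j in range(n) if mask[i, j]]
    vec = np.array([matrix[i, j] for i, j in idx])
    return vec, idx


def scatter_features(
    vector: np.ndarray, index: list[tuple[int, int]], n_rois: int
) -> np.ndarray:
    """Inverse of :func:`vectorize_connectivity`: place features back in a matrix."""
    out = np.zeros((n_rois, n_rois))
    for value, (i, j) in zip(vector, index, strict=True):
        out[i, j] = value
    return out


# ---------------------------------------------------------------------------
# cross-validated classification


def _labels(samples: list[CohortSample], label_field: str) -> np.ndarray:
    if label_field == "condition":
        return np.array([s.condition for s in samples])
    if label_field == "subject":
        return np.array([s.subject_id for s in samples])
    raise ValueError(f"unknown label field {label_field!r}")


def chance_level(labels: np.ndarray) -> float:
    """Majority-class frequency: accuracy of always predicting the mode."""
    _, counts = np.unique(labels, return_counts=True)
    return counts.max() / counts.sum()


def _make_classifier(name: str, knn_k: int = 1):
    if name == "mlr":
        # L2 regularization (sklearn default) with strength 1.0
        return LogisticRegression(C=1.0, max_iter=5000)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "knn":
        # distance = 1 - Pearson correlation between feature vectors
        return KNeighborsClassifier(
            n_neighbors=knn_k, metric="correlation", algorithm="brute"
        )
    raise ValueError(f"unknown classifier {name!r}")


def make_splits(
    samples: list[CohortSample],
    label_field: str,
    scheme: str,
    n_splits: int,
    seed: int,
    test_size: float = 0.2,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index pairs (train, test) for the requested cross-validation scheme.

    Condition labels use subject-grouped splits (a subject's sessions are
    never divided across train and test); subject labels use per-subject
    session splits, each subject contributing sessions to both sides.
    """
    subjects = np.array([s.subject_id for s in samples])
    if scheme == "shuffle80_20":
        if label_field == "condition":
            splitter = GroupShuffleSplit(
                n_splits=n_splits, test_size=test_size, random_state=seed
            )
            return [
                (tr, te)
                for tr, te in splitter.split(np.zeros(len(samples)), groups=subjects)
            ]
        # subject identification: split sessions within each subject
        rng = np.random.default_rng(seed)
        splits = []
        uniq = np.unique(subjects)
        for _ in range(n_splits):
            train_idx, test_idx = [], []
            for sub in uniq:
                idx = np.nonzero(subjects == sub)[0]
                perm = rng.permutation(idx)
                n_train = max(1, int(round((1 - test_size) * idx.size)))
                if n_train >= idx.size:
                    n_train = idx.size - 1
                train_idx.extend(perm[:n_train])
                test_idx.extend(perm[n_train:])
            splits.append((np.array(sorted(train_idx)), np.array(sorted(test_idx))))
        return splits
    if scheme == "leave_one_subject_out":
        if label_field == "subject":
            raise ValueError(
                "leave-one-subject-out is incompatible with subject identification "
                "(the held-out subject would be absent from training)"
            )
        logo = LeaveOneGroupOut()
        return [
            (tr, te)
            for tr, te in logo.split(np.zeros(len(samples)), groups=subjects)
        ]
    raise ValueError(f"unknown cross-validation scheme {scheme!r}")


def _run_split(
    x: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    classifier: str,
    standardize: bool,
    knn_k: int = 1,
) -> np.ndarray:
    """Fit on the train fold only and predict the test fold.

    Standardization parameters are computed from the train fold, so nothing
    in the test fold can influence the fitted model.
    """
    x_train, x_test = x[train], x[test]
    if standardize:
        scaler = StandardScaler().fit(x_train)
        x_train = scaler.transform(x_train)
        x_test = scaler.transform(x_test)
    clf = _make_classifier(classifier, knn_k)
    clf.fit(x_train, y[train])
    return clf.predict(x_test)


def classify_cv(
    samples: list[CohortSample],
    label_field: str = "condition",
    classifier: str = "mlr",
    scheme: str = "shuffle80_20",
    n_splits: int = 40,
    seed: int = 0,
    standardize: bool = True,
    knn_k: int = 1,
) -> ClassificationResult:
    """Cross-validated classification of conditions or subjects."""
    x = np.vstack([s.features for s in samples])
    y = _labels(samples, label_field)
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    splits = make_splits(samples, label_field, scheme, n_splits, seed)
    accuracies = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for train, test in splits:
        if len(np.unique(y[train])) < len(classes):
            raise ValueError(
                "a cross-validation split leaves a class absent from training"
            )
        pred = _run_split(x, y, train, test, classifier, standardize, knn_k)
        accuracies.append(float(np.mean(pred == y[test])))
        confusion += confusion_matrix(y[test], pred, labels=classes)
    accuracies = np.array(accuracies)
    return ClassificationResult(
        accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()),
        chance_level=chance_level(y),
        confusion=confusion,
        classes=classes,
        classifier_name=classifier,
        scheme_name=scheme,
        n_splits=len(splits),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# recursive feature elimination


def rfe_biomarker(
    samples: list[CohortSample],
    label_field: str = "condition",
    step: float = 0.05,
    scheme: str = "shuffle80_20",
    n_splits: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> BiomarkerRanking:
    """Rank features by recursive elimination with a logistic regression.

    At each round the MLR is fitted on each train fold of the CV scheme; the
    per-feature importance is the mean over folds of the class-maximum
    absolute coefficient, and the lowest ``step`` fraction of the remaining
    features (at least one) is eliminated.  The CV accuracy of the current
    feature set is recorded, giving the accuracy-vs-size curve; the support
    is the retained set at the accuracy maximum (smallest set on ties).
    Ranks reverse the elimination order (1 = survived longest).
    """
    x = np.vstack([s.features for s in samples])
    y = _labels(samples, label_field)
    n_feat = x.shape[1]
    if n_feat < 2:
        raise ValueError("RFE needs at least two features")
    splits = make_splits(samples, label_field, scheme, n_splits, seed)

    remaining = list(range(n_feat))
    elimination_order: list[int] = []  # first eliminated first
    curve: list[tuple[int, float]] = []
    support_sets: list[tuple[int, float, list[int]]] = []

    while remaining:
        cols = np.array(remaining)
        importances = np.zeros(cols.size)
        accs = []
        for train, test in splits:
            x_train, x_test = x[np.ix_(train, cols)], x[np.ix_(test, cols)]
            if standardize:
                scaler = StandardScaler().fit(x_train)
                x_train = scaler.transform(x_train)
                x_test = scaler.transform(x_test)
            clf = _make_classifier("mlr")
            clf.fit(x_train, y[train])
            importances += np.max(np.abs(clf.coef_), axis=0)
            accs.append(float(np.mean(clf.predict(x_test) == y[test])))
        importances /= len(splits)
        acc = float(np.mean(accs))
        curve.append((cols.size, acc))
        support_sets.append((cols.size, acc, list(remaining)))
        if cols.size == 1:
            elimination_order.append(remaining.pop())
            break
        n_drop = max(1, int(math.floor(step * cols.size)))
        drop_local = np.argsort(importances, kind="stable")[:n_drop]
        dropped = sorted((remaining[i] for i in drop_local))
        for f in dropped:
            remaining.remove(f)
        elimination_order.extend(dropped)

    rank = np.empty(n_feat, dtype=int)
    for order_pos, feat in enumerate(elimination_order):
        rank[feat] = n_feat - order_pos  # last eliminated gets rank 1
    best_acc = max(acc for _, acc, _ in support_sets)
    best = min(
        (size, feats) for size, acc, feats in support_sets if acc >= best_acc - 1e-12
    )
    support = np.zeros(n_feat, dtype=bool)
    support[best[1]] = True
    curve.sort()
    return BiomarkerRanking(rank=rank, support=support, accuracy_curve=curve)


# ---------------------------------------------------------------------------
# dimensionality reduction diagnostics


def reduce_and_silhouette(
    samples: list[CohortSample],
    method: str = "pca",
    n_components: int = 2,
    label_field: str = "condition",
) -> tuple[np.ndarray, float]:
    """Project features with PCA (unsupervised) or LDA (label-aware) and
    score the separation of the label clouds with the silhouette coefficient
    (Euclidean distance on the component coordinates; in [-1, 1])."""
    x = np.vstack([s.features for s in samples])
    y = _labels(samples, label_field)
    if n_components >= min(x.shape[1], len(samples) - 1):
        raise ValueError("n_components must be below min(n features, n samples - 1)")
    if method == "pca":
        coords = PCA(n_components=n_components).fit_transform(x)
    elif method == "lda":
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("LDA requires at least 2 samples per class")
        n_components = min(n_components, len(classes) - 1)
        coords = LinearDiscriminantAnalysis(n_components=n_components).fit_transform(
            x, y
        )
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return coords, float(silhouette_score(coords, y, metric="euclidean"))


# ---------------------------------------------------------------------------
# link-wise statistical testing


def linkwise_tests(
    samples: list[CohortSample],
    alpha: float = 0.05,
    test: str = "mannwhitneyu",
) -> LinkTestResult:
    """Per-link two-sample tests between conditions with multiple-comparison
    corrections.

    For each link, a two-sided Mann-Whitney test (or Welch t test) compares
    its values between every pair of conditions; with K > 2 conditions the
    smallest p value over the K(K-1)/2 pairs is retained per link.  The
    Bonferroni threshold is alpha / L over the L links; Benjamini-Hochberg
    rejections control the false-discovery rate at ``alpha``.
    """
    x = np.vstack([s.features for s in samples])
    conditions = np.array([s.condition for s in samples])
    classes = sorted(np.unique(conditions))
    if len(classes) < 2:
        raise ValueError("need at least two conditions")
    groups = {c: x[conditions == c] for c in classes}
    for c, g in groups.items():
        if g.shape[0] < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
    constant = np.nonzero(np.ptp(x, axis=0) == 0)[0]
    if constant.size:
        raise ValueError(
            "constant feature(s) at indices "
            f"{constant.tolist()}: rank tests are degenerate for constant links"
        )
    n_links = x.shape[1]
    pairs = [
        (classes[a], classes[b])
        for a in range(len(classes))
        for b in range(a + 1, len(classes))
    ]
    p_matrix = np.ones((len(pairs), n_links))
    for row, (ca, cb) in enumerate(pairs):
        ga, gb = groups[ca], groups[cb]
        if test == "mannwhitneyu":
            p_matrix[row] = stats.mannwhitneyu(
                ga, gb, alternative="two-sided", axis=0
            ).pvalue
        elif test == "welch":
            p_matrix[row] = stats.ttest_ind(ga, gb, equal_var=False, axis=0).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    p_values = p_matrix.min(axis=0)
    rejections = multipletests(p_values, alpha=alpha, method="fdr_bh")[0]
    return LinkTestResult(
        p_values=p_values,
        bonferroni_threshold=alpha / n_links,
        bh_rejections=rejections,
        n_pairs_tested=len(pairs),
        test_name=test,
    )


# ---------------------------------------------------------------------------
# study-design arithmetic


def split_collision_probability(
    n_groups: int, test_groups: int, n_repeats: int
) -> float:
    """Probability that repeated random test-set draws repeat an earlier split.

    With C(n_groups, test_groups) equally likely test sets and ``n_repeats``
    independent draws, the no-collision probability is the birthday product
    prod_{i<n_repeats} (1 - i / C); returns 1 minus that.
    """
    n_sets = math.comb(n_groups, test_groups)
    log_no_collision = sum(math.log1p(-i / n_sets) for i in range(n_repeats))
    return 1.0 - math.exp(log_no_collision)


def data_to_parameter_ratio(
    n_rois: int, n_timepoints: int, n_parameters: int
) -> int:
    """floor(number of data points / number of model parameters)."""
    return (n_rois * n_timepoints) // n_parameters
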