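"""Identification evaluation: classifiers, LOSO-CV, and open-set ROC.

The protocol mirrors common biometric-verification practice.  Each
(subject, session) is held out in turn — leave-one-session-out
cross-validation — so every fold tests cross-day generalisation, the
failure mode that session drift causes.  Within a fold a multiclass
classifier is trained on all remaining records and scores each held-out
record against every enrolled subject.

Scores are pooled across folds into genuine scores (the score a record's
true subject received) and impostor scores (all scores for wrong
subjects).  Sweeping an acceptance threshold over them yields the false
acceptance rate FAR (impostor score above threshold) and false rejection
rate FRR (genuine score below threshold); the equal error rate EER is the
crossing point and AUC the area under the (FAR, 1-FRR) curve.

Four classifier families are supported with fixed hyperparameters:
linear SVM (C=1, kernel scale 16), quadratic SVM (degree-2 polynomial
kernel, same C and scale), 1-nearest-neighbour with Euclidean distance,
and an ensemble of 30 bagged Gini decision trees capped at 2165 splits.
Native confidences are mapped to [0, 1] per class: a softmax over SVM
decision values, a softmax over negated nearest-per-class distances for
1-NN (raw 1-NN votes are 0/1 and cannot be swept), and vote fractions for
the bagged trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import BaggingClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import MeasurementRecord, SpectraDataset
from .features import (
    RatioCombinationSet,
    published_combination,
    ratiometric_transform,
    raw_features,
)

__all__ = [
    "ClassifierSpec",
    "ScoredPrediction",
    "RocResult",
    "loso_split",
    "fit_predict",
    "roc_from_scores",
    "evaluate",
    "finger_pair_classification",
]

_FAMILIES = ("linear-svm", "quadratic-svm", "knn", "bagged-trees")

#: short CLI aliases for the classifier families
FAMILY_ALIASES = {
    "lsvm": "linear-svm",
    "qsvm": "quadratic-svm",
    "knn": "knn",
    "bag": "bagged-trees",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its fixed hyperparameters."""

    family: str = "knn"
    box_constraint: float = 1.0  # SVM C
    kernel_scale: float = 16.0  # SVM feature scale divisor
    k_neighbors: int = 1  # KNN
    n_trees: int = 30  # bagged trees
    max_splits: int = 2165  # bagged trees: max internal splits per tree

    def __post_init__(self) -> None:
        family = FAMILY_ALIASES.get(self.family, self.family)
        if family not in _FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        object.__setattr__(self, "family", family)
        if min(self.box_constraint, self.kernel_scale) <= 0:
            raise ValueError("SVM hyperparameters must be > 0")
        if min(self.k_neighbors, self.n_trees, self.max_splits) < 1:
            raise ValueError("integer hyperparameters must be >= 1")


@dataclass(frozen=True)
class ScoredPrediction:
    """Per-class scores in [0, 1] for one validation record."""

    true_label: str
    classes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.scores):
            raise ValueError("one score per enrolled class required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def top_label(self) -> str:
        return self.classes[int(np.argmax(self.scores))]

    def accepted_label(self, threshold: float) -> str:
        """Open-set decision: the top class if its score clears ``threshold``,
        else the rejection label ``"reject"``."""
        i = int(np.argmax(self.scores))
        return self.classes[i] if self.scores[i] > threshold else "reject"


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep with FAR/FRR per threshold, EER (%) and AUC."""

    thresholds: tuple[float, ...]
    far: tuple[float, ...]
    frr: tuple[float, ...]
    eer: float
    auc: float


def loso_split(ds: SpectraDataset):
    """Leave-one-session-out folds.

    One fold per (subject, session): that subject's records from that
    session are the validation set; every other record (including other
    subjects' records from the same session label) trains.  Subjects with
    fewer than two sessions make cross-session validation impossible and
    are reported by name.
    """
    sessions_by_subject: dict[str, set[str]] = {}
    for r in ds.records:
        sessions_by_subject.setdefault(r.subject_id, set()).add(r.session_id)
    lonely = sorted(
        s for s, sess in sessions_by_subject.items() if len(sess) < 2
    )
    if lonely:
        raise ValueError(
            f"subjects with a single session cannot be split: {', '.join(lonely)}"
        )
    folds = []
    for subject in sorted(sessions_by_subject):
        for session in sorted(sessions_by_subject[subject]):
            val = ds.subset(
                lambda r, s=subject, d=session: r.subject_id == s
                and r.session_id == d
            )
            train = ds.subset(
                lambda r, s=subject, d=session: not (
                    r.subject_id == s and r.session_id == d
                )
            )
            folds.append((train, val))
    return folds


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _svm_scores(model: SVC, x: np.ndarray) -> np.ndarray:
    d = model.decision_function(x)
    if d.ndim == 1:  # binary: one margin, map to two-class decision values
        d = np.column_stack([-d, d])
    return _softmax(d)


def _knn_scores(
    x_train: np.ndarray, y_train: np.ndarray, x: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    # score_c = softmax over classes of (minus the Euclidean distance to
    # class c's nearest training point); monotone in 1-NN confidence.
    d = np.empty((x.shape[0], classes.size))
    for j, c in enumerate(classes):
        d[:, j] = cdist(x, x_train[y_train == c]).min(axis=1)
    return _softmax(-d)


def fit_predict(
    spec: ClassifierSpec,
    x_train: np.ndarray,
    y_train,
    x_val: np.ndarray,
    y_val,
    seed: int = 0,
) -> list[ScoredPrediction]:
    """Train ``spec`` and score every validation sample against every class."""
    x_train = np.asarray(x_train, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if x_train.shape[1] != x_val.shape[1]:
        raise ValueError("train/validation feature dimensions differ")

    if spec.family in ("linear-svm", "quadratic-svm"):
        # z-score on training statistics, then divide by the kernel scale:
        # the scale is defined relative to standardized features, which is
        # what makes one scale value meaningful for ohm-valued raw spectra
        # and order-one ratio features alike.
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd < 1e-12] = 1.0
        xs_train = (x_train - mu) / sd / spec.kernel_scale
        xs_val = (x_val - mu) / sd / spec.kernel_scale
        if spec.family == "linear-svm":
            model = SVC(
                kernel="linear",
                C=spec.box_constraint,
                decision_function_shape="ovr",
            )
        else:
            model = SVC(
                kernel="poly",
                degree=2,
                gamma=1.0,
                coef0=1.0,
                C=spec.box_constraint,
                decision_function_shape="ovr",
            )
        model.fit(xs_train, y_train)
        classes = model.classes_
        scores = _svm_scores(model, xs_val)
    elif spec.family == "knn":
        if spec.k_neighbors != 1:
            raise ValueError("only k=1 scoring is implemented")
        scores = _knn_scores(x_train, y_train, x_val, classes)
    else:  # bagged-trees
        model = BaggingClassifier(
            estimator=DecisionTreeClassifier(
                criterion="gini", max_leaf_nodes=spec.max_splits + 1
            ),
            n_estimators=spec.n_trees,
            random_state=seed,
        )
        model.fit(x_train, y_train)
        classes = model.classes_
        scores = model.predict_proba(x_val)

    cls = tuple(str(c) for c in classes)
    return [
        ScoredPrediction(
            true_label=str(y_val[i]),
            classes=cls,
            scores=tuple(float(v) for v in scores[i]),
        )
        for i in range(x_val.shape[0])
    ]


def _genuine_impostor(preds: list[ScoredPrediction]) -> tuple[np.ndarray, np.ndarray]:
    genuine, impostor = [], []
    for p in preds:
        for c, s in zip(p.classes, p.scores):
            (genuine if c == p.true_label else impostor).append(s)
    return np.asarray(genuine, float), np.asarray(impostor, float)


def roc_from_scores(preds: list[ScoredPrediction]) -> RocResult:
    """ROC over pooled genuine/impostor scores.

    FAR(t) is the fraction of impostor scores >= t; FRR(t) the fraction of
    genuine scores < t.  Thresholds sweep the sorted score set plus a
    sentinel above the maximum, so the curve runs from (FAR=1, FRR=0) to
    (FAR=0, FRR=1).  EER interpolates linearly between the two thresholds
    bracketing the FAR=FRR crossing; AUC is the trapezoid area under
    (FAR, 1-FRR).
    """
    genuine, impostor = _genuine_impostor(preds)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need at least one genuine and one impostor score")

    all_scores = np.concatenate([genuine, impostor])
    thresholds = np.unique(all_scores)
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)

    far = np.array([(impostor >= t).mean() for t in thresholds])
    frr = np.array([(genuine < t).mean() for t in thresholds])

    # FAR is non-increasing and FRR non-decreasing in t; find the sign
    # change of (FAR - FRR) and interpolate both linearly in t.
    diff = far - frr
    idx = int(np.argmax(diff <= 0))
    if idx == 0:
        eer = float(far[0])
    else:
        d1, d2 = diff[idx - 1], diff[idx]
        t = 0.0 if d1 == d2 else d1 / (d1 - d2)
        eer = float(far[idx - 1] + t * (far[idx] - far[idx - 1]))

    # traverse in decreasing threshold order, along which FAR and the true
    # acceptance rate 1-FRR are both non-decreasing
    auc = float(np.trapezoid((1.0 - frr)[::-1], far[::-1]))

    return RocResult(
        thresholds=tuple(float(t) for t in thresholds),
        far=tuple(float(v) for v in far),
        frr=tuple(float(v) for v in frr),
        eer=100.0 * eer,
        auc=auc,
    )


def _featurize(
    records, feature_kind: str, combos: RatioCombinationSet
) -> np.ndarray:
    if feature_kind == "raw":
        return np.array([raw_features(r).as_array() for r in records])
    if feature_kind == "ratiometric":
        return np.array(
            [ratiometric_transform(r, combos).as_array() for r in records]
        )
    raise ValueError(f"unknown feature kind {feature_kind!r}")


@dataclass(frozen=True)
class EvaluationResult:
    """Pooled LOSO-CV outcome for one feature kind and classifier."""

    accuracy: float  # percent, top-score class with no threshold
    eer: float  # percent
    auc: float
    confusion: np.ndarray = field(repr=False)  # rows true, cols predicted
    classes: tuple[str, ...] = ()
    n_folds: int = 0
    n_records: int = 0
    roc: RocResult | None = field(default=None, repr=False)

    @property
    def error_rate(self) -> float:
        return 100.0 - self.accuracy


def evaluate(
    ds: SpectraDataset,
    feature_kind: str = "ratiometric",
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    combos: RatioCombinationSet | None = None,
    unknown_attacker: bool = False,
) -> EvaluationResult:
    """LOSO-CV subject identification on ``ds``.

    Featurizes every record, runs every leave-one-session-out fold with
    ``spec``, pools the scored predictions, and reports closed-set
    accuracy (top score, no threshold), pooled EER/AUC, and the subject
    confusion matrix.

    With ``unknown_attacker=True`` the ROC pool additionally contains, for
    each subject, the scores their records receive from a model trained
    with that subject left out entirely — probes by users who were never
    enrolled, which can only be scored as impostors.  Accuracy and the
    confusion matrix stay closed-set.
    """
    spec = spec or ClassifierSpec()
    combos = combos or published_combination()
    classes = ds.subject_ids
    class_index = {c: i for i, c in enumerate(classes)}

    preds: list[ScoredPrediction] = []
    folds = loso_split(ds)
    for train, val in folds:
        x_train = _featurize(train.records, feature_kind, combos)
        x_val = _featurize(val.records, feature_kind, combos)
        y_train = [r.subject_id for r in train.records]
        y_val = [r.subject_id for r in val.records]
        preds.extend(fit_predict(spec, x_train, y_train, x_val, y_val, seed=seed))

    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    correct = 0
    for p in preds:
        pred = p.top_label
        confusion[class_index[p.true_label], class_index[pred]] += 1
        correct += pred == p.true_label
    n_closed = len(preds)

    if unknown_attacker:
        for subject in classes:
            train = ds.subset(lambda r, s=subject: r.subject_id != s)
            probe = ds.subset(lambda r, s=subject: r.subject_id == s)
            x_train = _featurize(train.records, feature_kind, combos)
            x_probe = _featurize(probe.records, feature_kind, combos)
            y_train = [r.subject_id for r in train.records]
            y_probe = [r.subject_id for r in probe.records]
            preds.extend(
                fit_predict(spec, x_train, y_train, x_probe, y_probe, seed=seed)
            )

    roc = roc_from_scores(preds)
    return EvaluationResult(
        accuracy=100.0 * correct / n_closed,
        eer=roc.eer,
        auc=roc.auc,
        confusion=confusion,
        classes=classes,
        n_folds=len(folds),
        n_records=n_closed,
        roc=roc,
    )


def finger_pair_classification(
    ds: SpectraDataset,
    feature_kind: str = "ratiometric",
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    combos: RatioCombinationSet | None = None,
) -> float:
    """LOSO-CV accuracy (%) at telling the ten finger pairs apart.

    Single-subject mode: each sample is one pair's 25-point raw spectrum
    (``feature_kind="raw"``, label = finger pair) or one combination's
    25-point ratio curve (``feature_kind="ratiometric"``, label =
    combination index).
    """
    subjects = ds.subject_ids
    if len(subjects) != 1:
        raise ValueError(
            f"finger-pair classification takes a single-subject dataset, "
            f"got subjects {subjects}"
        )
    spec = spec or ClassifierSpec()
    combos = combos or published_combination()

    def samples(records) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for r in records:
            if feature_kind == "raw":
                for p, sp in sorted(r.spectra.items()):
                    xs.append(sp.as_array())
                    ys.append(str(p))
            elif feature_kind == "ratiometric":
                v = ratiometric_transform(r, combos).as_array().reshape(10, -1)
                for ci in range(10):
                    xs.append(v[ci])
                    ys.append(f"combo{ci}")
            else:
                raise ValueError(f"unknown feature kind {feature_kind!r}")
        return np.array(xs), np.array(ys)

    correct = total = 0
    for train, val in loso_split(ds):
        x_train, y_train = samples(train.records)
        x_val, y_val = samples(val.records)
        preds = fit_predict(spec, x_train, y_train, x_val, y_val, seed=seed)
        correct += sum(p.top_label == p.true_label for p in preds)
        total += len(preds)
    return 100.0 * correct / total
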