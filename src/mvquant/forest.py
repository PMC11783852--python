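"""Random-forest pixel classifier producing per-class probability maps.

The classifier is trained on ellipse-annotated pixels (three classes:
background, isolated microvessel, vessel agglomerate) described by the
multi-scale feature stack, and predicts a posterior probability for each
class at every pixel of a new image. Posteriors are soft votes — the average
of the trees' leaf class frequencies — which renders as a smooth
"probabilistic map": the brighter a pixel, the higher the class posterior.

Training is fully reproducible: (training set, hyperparameters, seed)
determine the model, and the model determines every map.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .annotations import CLASS_LABELS, TrainingSet
from .errors import (
    FormatError,
    IncompleteTrainingSetError,
    LeakageError,
    ParameterError,
)
from .features import DEFAULT_SIGMAS, MultiscaleFeatureExtractor
from .image_io import GrayImage
from .metrics import (
    PerformanceCurves,
    confusion_from_labels,
    fallout,
    fmeasure,
    precision,
    recall,
    roc_curve,
    threshold_stat,
)

__all__ = [
    "ProbabilityMap",
    "PixelForestClassifier",
    "train",
    "predict_maps",
    "learning_curve",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-class posterior raster for one image.

    ``probs`` holds values in [0, 1]; ``gray_render`` rescales them to the
    8-bit display convention round(255 * p), rounding halves up, so white
    marks certain membership.
    """

    class_label: int
    probs: np.ndarray
    image_id: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2:
            raise FormatError("ProbabilityMap requires a 2-D raster")
        if p.min() < 0 or p.max() > 1:
            raise FormatError("posterior probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)

    @property
    def gray_render(self) -> np.ndarray:
        return np.floor(255.0 * self.probs + 0.5).astype(np.uint8)


class PixelForestClassifier(ClassifierMixin, BaseEstimator):
    """Bagged decision-tree ensemble over multi-scale pixel features.

    Parameters
    ----------
    n_trees : int, default 200
        Ensemble size. The cumulative tree count doubles as the "epoch"
        axis of :func:`learning_curve`.
    max_depth : int or None, default None
        Tree depth limit; None grows trees until pure.
    sigmas : tuple of float
        Gaussian scales of the feature stack (see
        :class:`~mvquant.features.MultiscaleFeatureExtractor`).
    bootstrap : bool, default True
        Bagging on/off; each split considers ceil(sqrt(d)) random features
        either way.
    random_state : int, default 0
        Seed; identical (data, params, seed) give identical models.

    Attributes
    ----------
    forest_ : fitted sklearn RandomForestClassifier
    classes_ : class labels seen during fit
    training_accuracy_ : float, resubstitution accuracy on the fit data
    """

    def __init__(
        self,
        n_trees: int = 200,
        max_depth: int | None = None,
        sigmas: tuple[float, ...] = DEFAULT_SIGMAS,
        bootstrap: bool = True,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.sigmas = tuple(float(s) for s in sigmas)
        self.bootstrap = bootstrap
        self.random_state = random_state

    @property
    def extractor(self) -> MultiscaleFeatureExtractor:
        return MultiscaleFeatureExtractor(sigmas=self.sigmas)

    def _make_forest(self, n_estimators: int, warm_start: bool = False) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=self.max_depth,
            max_features="sqrt",
            bootstrap=self.bootstrap,
            random_state=self.random_state,
            warm_start=warm_start,
            n_jobs=1,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PixelForestClassifier":
        if self.n_trees < 1:
            raise ParameterError(f"n_trees must be >= 1, got {self.n_trees}")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
            raise ParameterError("fit requires a non-empty (n, d) X and matching y")
        self.forest_ = self._make_forest(self.n_trees)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self.training_accuracy_ = float(self.forest_.score(X, y))
        return self

    def fit_training_set(self, ts: TrainingSet) -> "PixelForestClassifier":
        """Fit from an annotation-derived :class:`TrainingSet`.

        Requires all three classes to be represented.
        """
        missing = set(CLASS_LABELS) - set(ts.class_counts)
        if missing:
            raise IncompleteTrainingSetError(missing)
        expected = tuple(self.extractor.feature_names)
        if ts.feature_names != expected:
            raise FormatError(
                "training set features do not match this classifier's "
                f"extractor config: {ts.feature_names} vs {expected}"
            )
        return self.fit(ts.X, ts.y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(X)

    def predict_maps(self, img: GrayImage) -> dict[int, ProbabilityMap]:
        """Per-class posterior maps for one image.

        Returns a dict keyed by class label. Per pixel, the posteriors over
        all classes sum to 1.
        """
        check_is_fitted(self, "forest_")
        feats = self.extractor.transform_flat(img)
        proba = self.forest_.predict_proba(feats)
        h, w = img.pixels.shape
        return {
            int(cls): ProbabilityMap(
                class_label=int(cls),
                probs=proba[:, i].reshape(h, w),
                image_id=img.source_id,
            )
            for i, cls in enumerate(self.classes_)
        }


def train(
    ts: TrainingSet,
    n_trees: int = 200,
    seed: int = 0,
    max_depth: int | None = None,
    sigmas: tuple[float, ...] | None = None,
) -> PixelForestClassifier:
    """Train a pixel classifier on an annotation-derived training set."""
    if n_trees < 1:
        raise ParameterError(f"n_trees must be >= 1, got {n_trees}")
    clf = PixelForestClassifier(
        n_trees=n_trees,
        max_depth=max_depth,
        sigmas=sigmas if sigmas is not None else DEFAULT_SIGMAS,
        random_state=seed,
    )
    return clf.fit_training_set(ts)


def predict_maps(model: PixelForestClassifier, img: GrayImage) -> dict[int, ProbabilityMap]:
    return model.predict_maps(img)


def learning_curve(
    ts: TrainingSet,
    eval_set: TrainingSet,
    tree_counts: list[int],
    seed: int = 0,
    positive: int = 2,
    max_depth: int | None = None,
) -> PerformanceCurves:
    """Held-out metric trajectories versus cumulative tree count.

    A single tree sequence is grown incrementally (warm start at a fixed
    seed), so every smaller ensemble is a prefix of every larger one. At
    each requested count the five confusion metrics are recorded for the
    positive class (one-vs-rest, argmax predictions) on the evaluation
    pixels; the ROC uses the final ensemble's positive-class scores.

    Raises
    ------
    LeakageError
        If any (image, pixel) appears in both the training and the
        evaluation set.
    """
    counts = sorted(set(int(c) for c in tree_counts))
    if not counts or counts[0] < 1:
        raise ParameterError(f"tree_counts must be positive integers, got {tree_counts}")
    shared = ts.pixel_keys & eval_set.pixel_keys
    if shared:
        raise LeakageError(
            f"{len(shared)} pixel(s) appear in both the training and "
            f"evaluation sets, e.g. {sorted(shared)[0]}"
        )
    if ts.feature_names != eval_set.feature_names:
        raise FormatError("training and evaluation feature configurations differ")

    proto = PixelForestClassifier(
        n_trees=counts[-1], max_depth=max_depth, random_state=seed
    )
    forest = proto._make_forest(counts[0], warm_start=True)
    rows: list[tuple[float, float, float, float, float]] = []
    for n in counts:
        forest.set_params(n_estimators=n)
        forest.fit(ts.X, ts.y)
        pred = forest.predict(eval_set.X)
        c = confusion_from_labels(eval_set.y, pred, positive=positive)
        rows.append((precision(c), recall(c), fmeasure(c), fallout(c), threshold_stat(c)))
    pos_col = int(np.nonzero(forest.classes_ == positive)[0][0])
    scores = forest.predict_proba(eval_set.X)[:, pos_col]
    points, auc = roc_curve(scores, eval_set.y == positive)
    p, r, f, fo, t = zip(*rows)
    return PerformanceCurves(
        epochs=tuple(counts),
        precision=p,
        recall=r,
        fmeasure=f,
        fallout=fo,
        threshold_stat=t,
        roc_points=points,
        auc=auc,
    )


def save_model(model: PixelForestClassifier, path) -> None:
    """Persist a fitted classifier as a single self-describing file."""
    check_is_fitted(model, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "feature_names": tuple(model.extractor.feature_names),
        "classes": np.asarray(model.classes_),
        "training_accuracy": model.training_accuracy_,
        "forest": model.forest_,
        "n_features_in": model.n_features_in_,
    }
    joblib.dump(payload, path, compress=3)


def load_model(path) -> PixelForestClassifier:
    """Load a persisted classifier, refusing incompatible feature configs."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise FormatError(f"cannot load model {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise FormatError(f"{path} is not an mvquant model file (version mismatch)")
    model = PixelForestClassifier(**payload["params"])
    stored = tuple(payload["feature_names"])
    expected = tuple(model.extractor.feature_names)
    if stored != expected:
        raise FormatError(
            f"model feature configuration mismatch: file declares {stored}, "
            f"sigmas {model.sigmas} imply {expected}"
        )
    model.forest_ = payload["forest"]
    model.classes_ = payload["classes"]
    model.training_accuracy_ = payload["training_accuracy"]
    model.n_features_in_ = payload["n_features_in"]
    return model
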