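"""Linear discriminant fitting, projection, and classification.

The discriminant axes solve the generalized eigenproblem of between-class
versus pooled within-class scatter, Sw^-1 Sb, keeping at most k - 1 axes for
k classes.  Eigenvectors are Sw-orthonormal, so the pooled within-class
covariance in discriminant space is the identity (up to any ridge applied);
classification is then nearest-centroid with a log-prior offset, which is
exactly the Gaussian discriminant rule under the shared-covariance model.

Conventions (fixed so fits are bit-deterministic):

* Sb weights class centroids by class frequency; priors are empirical class
  frequencies by default (``priors="uniform"`` available).
* If Sw is ill-conditioned (condition number > 1e12), a ridge of
  ``eps * trace(Sw)/p`` is added to its diagonal and logged -- never a
  silent failure.  The subset search deliberately fits many tiny, sometimes
  collinear feature pairs, so this path is routine there.
* Each scaling column is flipped so its largest-magnitude loading is
  positive, making plots and serialized models reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.model_selection import StratifiedKFold

from .containers import CellMatrix, Embedding, LabelVector

logger = logging.getLogger(__name__)

__all__ = [
    "DiscriminantModel",
    "fit_lda",
    "transform",
    "classify",
    "crossvalidate",
    "CrossValResult",
]

#: condition-number threshold beyond which Sw gets a ridge
COND_THRESHOLD = 1e12
#: ridge fraction of mean diagonal, applied when Sw is ill-conditioned
RIDGE_EPS = 1e-8


@dataclass
class DiscriminantModel:
    """A fitted discriminant model; supports transform/classify on unseen data.

    Attributes
    ----------
    feature_subset : ordered feature names the model consumes.
    scalings : (p_sub, d) matrix mapping centred feature space to LD space.
    class_centroids : (k, d) class means in LD space.
    priors : length-k class frequencies (sum to 1).
    global_means : length-p_sub feature means used for centring.
    eigenvalues : length-d discriminability of each axis, non-increasing.
    ridge : the ridge actually added to Sw's diagonal (0.0 if none).
    classes : class names in tie-break order.
    """

    feature_subset: list[str]
    scalings: np.ndarray
    class_centroids: np.ndarray
    priors: np.ndarray
    global_means: np.ndarray
    eigenvalues: np.ndarray
    ridge: float
    classes: list[str]
    cyclic: bool = False

    @property
    def n_axes(self) -> int:
        return self.scalings.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def loadings(self) -> pd.DataFrame:
        """Per-feature LD coefficients -- the interpretability surface."""
        return pd.DataFrame(
            self.scalings,
            index=self.feature_subset,
            columns=[f"LD{i + 1}" for i in range(self.n_axes)],
        )

    def to_json(self, path) -> None:
        payload = {
            "feature_subset": self.feature_subset,
            "scalings": self.scalings.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "priors": self.priors.tolist(),
            "global_means": self.global_means.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "ridge": self.ridge,
            "classes": self.classes,
            "cyclic": self.cyclic,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_subset=list(d["feature_subset"]),
            scalings=np.asarray(d["scalings"], dtype=float),
            class_centroids=np.asarray(d["class_centroids"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            global_means=np.asarray(d["global_means"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            ridge=float(d["ridge"]),
            classes=list(d["classes"]),
            cyclic=bool(d.get("cyclic", False)),
        )


def _scatter_matrices(
    X: np.ndarray, codes: np.ndarray, k: int, priors: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    means = np.vstack([X[codes == c].mean(axis=0) for c in range(k)])
    xbar = priors @ means
    Sw = np.zeros((p, p))
    for c in range(k):
        Xc = X[codes == c] - means[c]
        Sw += Xc.T @ Xc
    Sw /= n - k
    dm = (means - xbar) * np.sqrt(priors)[:, None]
    Sb = dm.T @ dm
    return Sw, Sb, means, xbar


def fit_lda(
    m: CellMatrix,
    y: LabelVector,
    features: list[str] | None = None,
    priors: str = "empirical",
    ridge_eps: float = RIDGE_EPS,
) -> DiscriminantModel:
    """Fit discriminant axes from labelled data.

    Parameters
    ----------
    m, y : training matrix and per-cell class labels (every class needs
        at least 2 cells).
    features : optional ordered subset of feature names; defaults to all.
    priors : ``"empirical"`` (class frequencies, default) or ``"uniform"``.
    ridge_eps : ridge fraction applied when Sw is ill-conditioned.

    Returns a :class:`DiscriminantModel` with ``min(k - 1, p_sub)`` axes
    ordered by decreasing eigenvalue.
    """
    if len(y) != m.n_cells:
        raise ValueError("labels length does not match matrix rows")
    sub = m if features is None else m.select_features(list(features))
    X = sub.values
    codes = y.codes()
    k = y.n_classes
    counts = y.counts()
    if (counts < 2).any():
        small = [y.classes[c] for c in np.flatnonzero(counts < 2)]
        raise ValueError(f"every class needs >= 2 cells; too small: {small}")

    if priors == "empirical":
        pri = counts / counts.sum()
    elif priors == "uniform":
        pri = np.full(k, 1.0 / k)
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")

    Sw, Sb, means, xbar = _scatter_matrices(X, codes, k, pri)

    ridge = 0.0
    p_sub = X.shape[1]
    trace = np.trace(Sw)
    evals_w = np.linalg.eigvalsh(Sw)
    cond = np.inf if evals_w[0] <= 0 else evals_w[-1] / evals_w[0]
    if cond > COND_THRESHOLD:
        if trace <= 0:
            raise np.linalg.LinAlgError(
                "within-class scatter is identically zero; cannot fit"
            )
        ridge = ridge_eps * trace / p_sub
        logger.warning(
            "within-class scatter ill-conditioned (cond=%.3g); "
            "applying ridge %.3g to its diagonal",
            cond,
            ridge,
        )
        Sw = Sw + ridge * np.eye(p_sub)

    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        # escalate the ridge once before giving up
        ridge = max(ridge, 1e-4 * trace / p_sub) if trace > 0 else 1e-12
        Sw = Sw + ridge * np.eye(p_sub)
        logger.warning("generalized eigensolver failed; retrying with ridge %.3g", ridge)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)

    d = min(k - 1, p_sub)
    order = np.argsort(evals)[::-1][:d]
    evals = np.maximum(evals[order], 0.0)
    scalings = evecs[:, order]
    # deterministic sign: largest-|loading| entry of each axis is positive
    for j in range(d):
        i = int(np.argmax(np.abs(scalings[:, j])))
        if scalings[i, j] < 0:
            scalings[:, j] = -scalings[:, j]

    centroids = (means - xbar) @ scalings
    return DiscriminantModel(
        feature_subset=list(sub.feature_names),
        scalings=scalings,
        class_centroids=centroids,
        priors=pri,
        global_means=xbar,
        eigenvalues=evals,
        ridge=ridge,
        classes=list(y.classes),
        cyclic=y.cyclic,
    )


def transform(model: DiscriminantModel, m: CellMatrix) -> Embedding:
    """Project (possibly unseen) cells onto the trained LD axes.

    Pure matrix math -- no refitting -- so held-out cells land on the same
    axes as the training data.  Extra features in ``m`` are ignored; missing
    ones raise with their names.
    """
    missing = [f for f in model.feature_subset if f not in m.feature_names]
    if missing:
        raise KeyError(f"matrix lacks model features: {missing}")
    idx = [m.feature_names.index(f) for f in model.feature_subset]
    coords = (m.values[:, idx] - model.global_means) @ model.scalings
    return Embedding(coords, list(m.cell_ids))


def classify(model: DiscriminantModel, m: CellMatrix) -> LabelVector:
    """Assign each cell the class with the best Gaussian discriminant score.

    In LD space the pooled within-class covariance is the identity, so the
    score is ``-0.5 ||z - centroid_c||^2 + log prior_c``; ties go to the
    first class in ``model.classes`` order.
    """
    z = transform(model, m).coords
    d2 = ((z[:, None, :] - model.class_centroids[None, :, :]) ** 2).sum(axis=2)
    scores = -0.5 * d2 + np.log(model.priors)[None, :]
    best = np.argmax(scores, axis=1)  # argmax takes the first max: tie-break
    return LabelVector(
        np.asarray(model.classes)[best], list(model.classes), model.cyclic
    )


@dataclass
class CrossValResult:
    """Stratified k-fold classification summary."""

    accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame  # rows = truth, columns = prediction
    n_errors: int
    n_cells: int
    adjacent_error_fraction: float | None = None
    predictions: pd.DataFrame = field(repr=False, default=None)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"accuracy: {self.accuracy:.4f}  ({self.n_cells - self.n_errors}"
                 f"/{self.n_cells} cells)"]
        if self.adjacent_error_fraction is not None:
            lines.append(
                f"errors in an adjacent phase: {self.adjacent_error_fraction:.4f}"
            )
        return "\n".join(lines)


def crossvalidate(
    m: CellMatrix,
    y: LabelVector,
    folds: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
    priors: str = "empirical",
) -> CrossValResult:
    """Stratified k-fold cross-validated classification.

    Splits the cells into ``folds`` non-overlapping, class-stratified test
    sets, refits on each training portion and classifies the held-out cells.
    For cyclic labels the summary additionally reports the fraction of
    misclassified cells whose predicted phase is adjacent (mod k) to the
    truth -- on a continuous process these are transitional cells rather
    than genuine mistakes.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = y.counts()
    if (counts < folds).any():
        small = [y.classes[c] for c in np.flatnonzero(counts < folds)]
        raise ValueError(
            f"classes {small} have fewer cells than folds={folds}; "
            "stratification impossible -- reduce folds"
        )
    codes = y.codes()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(m.n_cells, dtype=object)
    for train_idx, test_idx in skf.split(np.zeros(m.n_cells), codes):
        model = fit_lda(m.select_cells(train_idx), y.select(train_idx),
                        features=features, priors=priors)
        pred[test_idx] = classify(model, m.select_cells(test_idx)).labels
    pred = pred.astype(str)

    truth = y.labels
    correct = pred == truth
    acc = float(correct.mean())
    per_class = {
        c: float(correct[truth == c].mean()) for c in y.classes
    }
    conf = pd.crosstab(
        pd.Categorical(truth, categories=y.classes),
        pd.Categorical(pred, categories=y.classes),
        dropna=False,
    )
    conf.index = pd.Index(y.classes, name="truth")
    conf.columns = pd.Index(y.classes, name="predicted")

    adjacent = None
    n_err = int((~correct).sum())
    if y.cyclic:
        if n_err == 0:
            adjacent = 1.0
        else:
            adj = [
                y.is_adjacent(t, p)
                for t, p in zip(truth[~correct], pred[~correct])
            ]
            adjacent = float(np.mean(adj))
    preds = pd.DataFrame({"cell_id": m.cell_ids, "truth": truth, "predicted": pred})
    return CrossValResult(
        accuracy=acc,
        per_class_accuracy=per_class,
        confusion=conf,
        n_errors=n_err,
        n_cells=m.n_cells,
        adjacent_error_fraction=adjacent,
        predictions=preds,
    )
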