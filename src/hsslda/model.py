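"""Model/Results façade over the discriminant and subset-search machinery.

Usage mirrors the statsmodels idiom: build a model object from data, call
``fit()``, work with the returned results object::

    from hsslda import HSSLDA, synthetic

    m, y = synthetic.make_blobs(synthetic.BlobSpec(seed=1))
    res = HSSLDA(m, y, metric="euclidean").fit()
    print(res.summary())
    coords = res.transform(new_matrix)          # out-of-sample projection
    predicted = res.classify(new_matrix)        # Gaussian discriminant rule
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import lda as _lda
from .containers import CellMatrix, Embedding, LabelVector
from .hss import HSSTrace, hss_select
from .io import load_matrix
from .metrics import get_metric

__all__ = ["LDA", "HSSLDA", "LDAResults", "HSSLDAResults"]


class LDA:
    """Linear discriminant model on a labelled cell matrix.

    Parameters
    ----------
    matrix, labels : training data (see :class:`~hsslda.containers.CellMatrix`
        and :class:`~hsslda.containers.LabelVector`).
    features : optional ordered feature subset; defaults to every column.
    priors : "empirical" class frequencies (default) or "uniform".
    """

    def __init__(
        self,
        matrix: CellMatrix,
        labels: LabelVector,
        features: list[str] | None = None,
        priors: str = "empirical",
    ):
        self.matrix = matrix
        self.labels = labels
        self.features = features
        self.priors = priors

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "label", cyclic: bool = False, **kw
    ) -> "LDA":
        y = LabelVector(df[label_column].to_numpy(), cyclic=cyclic)
        m = CellMatrix.from_dataframe(
            df.drop(columns=[label_column]).astype(float)
        )
        return cls(m, y, **kw)

    @classmethod
    def from_csv(cls, path, label_column: str = "label", cyclic: bool = False, **kw):
        m, y = load_matrix(path, label_column=label_column, cyclic=cyclic)
        return cls(m, y, **kw)

    def fit(self) -> "LDAResults":
        model = _lda.fit_lda(
            self.matrix, self.labels, features=self.features, priors=self.priors
        )
        return LDAResults(self, model)

    def crossvalidate(self, folds: int = 10, seed: int = 0) -> _lda.CrossValResult:
        """Stratified k-fold classification accuracy (refits per fold)."""
        return _lda.crossvalidate(
            self.matrix, self.labels, folds=folds, seed=seed,
            features=self.features, priors=self.priors,
        )


class HSSLDA(LDA):
    """LDA with hybrid subset selection of the feature set.

    ``fit()`` runs the full stepwise search scored by ``metric`` (a registry
    name such as "euclidean", "silhouette", "pce", "pixeldensity",
    "custom:<path>", or a SeparationMetric object) and returns results for
    the elbow-selected final model, trace included.
    """

    def __init__(
        self,
        matrix: CellMatrix,
        labels: LabelVector,
        metric="euclidean",
        features: list[str] | None = None,
        priors: str = "empirical",
        allow_large: bool = False,
        normalize_elbow: bool = True,
    ):
        super().__init__(matrix, labels, features=features, priors=priors)
        self.metric = get_metric(metric)
        self.allow_large = allow_large
        self.normalize_elbow = normalize_elbow

    def fit(self) -> "HSSLDAResults":
        model, trace = hss_select(
            self.matrix,
            self.labels,
            metric=self.metric,
            features=self.features,
            allow_large=self.allow_large,
            normalize_elbow=self.normalize_elbow,
        )
        return HSSLDAResults(self, model, trace)


class LDAResults:
    """Fitted discriminant axes plus everything derived from them."""

    def __init__(self, parent: LDA, model: _lda.DiscriminantModel):
        self.parent = parent
        self.model = model
        self._embedding: Embedding | None = None

    # -- core accessors -------------------------------------------------
    @property
    def eigenvalues(self) -> np.ndarray:
        return self.model.eigenvalues

    @property
    def explained_ratio(self) -> np.ndarray:
        ev = self.model.eigenvalues
        total = ev.sum()
        return ev / total if total > 0 else ev

    @property
    def loadings(self) -> pd.DataFrame:
        return self.model.loadings()

    @property
    def embedding(self) -> Embedding:
        """Training cells on the fitted axes (computed once, cached)."""
        if self._embedding is None:
            self._embedding = _lda.transform(self.model, self.parent.matrix)
        return self._embedding

    # -- operations on (possibly unseen) data ---------------------------
    def transform(self, m: CellMatrix | None = None) -> Embedding:
        """Project cells onto the trained axes without refitting."""
        return _lda.transform(self.model, m if m is not None else self.parent.matrix)

    def classify(self, m: CellMatrix | None = None) -> LabelVector:
        return _lda.classify(self.model, m if m is not None else self.parent.matrix)

    def score(self, metric="euclidean") -> float:
        """Separation metric evaluated on the training embedding."""
        return get_metric(metric).evaluate(self.embedding, self.parent.labels)

    def init_coordinates(self) -> pd.DataFrame:
        """First two LDs per cell, for initializing an external embedder
        (e.g. passed to UMAP's ``init=`` as a plain matrix)."""
        if self.model.n_axes < 2:
            raise ValueError(
                "2-D initialization needs >= 2 discriminants (k >= 3 classes)"
            )
        return self.embedding.to_dataframe().iloc[:, :2]

    def save(self, path) -> None:
        self.model.to_json(path)

    def plot(self, ax=None):
        """Biaxial scatter of the training embedding coloured by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        xy = self.embedding.biaxial()
        for c in self.parent.labels.classes:
            mask = self.parent.labels.labels == c
            ax.scatter(xy[mask, 0], xy[mask, 1], s=4, label=c)
        ax.set_xlabel("LD1")
        ax.set_ylabel("LD2" if self.embedding.n_axes > 1 else "")
        ax.legend(markerscale=3, fontsize=8)
        return ax

    def summary(self) -> str:
        mdl = self.model
        lines = [
            "Linear discriminant analysis",
            "=" * 60,
            f"cells: {self.parent.matrix.n_cells}    classes: {mdl.n_classes}"
            f"    features used: {len(mdl.feature_subset)}"
            f"    discriminants: {mdl.n_axes}",
            f"priors: {self.parent.priors}    ridge applied: {mdl.ridge:.3g}",
            "",
            "axis   eigenvalue   explained",
        ]
        for i, (ev, ex) in enumerate(zip(mdl.eigenvalues, self.explained_ratio)):
            lines.append(f"LD{i + 1:<4} {ev:>10.4f}   {ex:>8.1%}")
        lines += ["", "loadings (features x LDs):", self.loadings.round(4).to_string()]
        return "\n".join(lines)


class HSSLDAResults(LDAResults):
    """Results of the elbow-selected model, with the full search trace."""

    def __init__(self, parent: HSSLDA, model: _lda.DiscriminantModel, trace: HSSTrace):
        super().__init__(parent, model)
        self.trace = trace

    @property
    def selected_features(self) -> list[str]:
        return list(self.trace.final_features)

    def summary(self) -> str:
        sizes, curve = self.trace.size_curve()
        head = [
            "Hybrid subset selection + linear discriminant analysis",
            "=" * 60,
            f"metric: {self.trace.metric_name}    fits performed: "
            f"{self.trace.n_fits}    subsets traced: {len(self.trace.evaluated)}",
            f"elbow size: {self.trace.elbow_size} of {max(sizes)} features",
            f"selected features: {', '.join(self.selected_features)}",
            "",
            "best oriented score per size:",
        ]
        for s, v in zip(sizes, curve):
            mark = "  <- elbow" if s == self.trace.elbow_size else ""
            head.append(f"  {s:>3}  {v:.6f}{mark}")
        return "\n".join(head + ["", super().summary()])
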