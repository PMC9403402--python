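"""Core in-memory containers shared by every module.

A :class:`CellMatrix` is the universal input: a dense cells x features table
with unique feature names and cell IDs.  A :class:`LabelVector` carries the
supervision signal -- one categorical class per cell, with an explicit class
order and an optional flag marking that order as circular (cell-cycle style).
An :class:`Embedding` holds per-cell discriminant coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellMatrix", "LabelVector", "TransformSpec", "Embedding"]


def _check_unique(names: list[str], what: str) -> None:
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CellMatrix:
    """Dense n x p expression table.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_features)
        Numeric matrix; must be finite (no NaN/inf) after loading.
    feature_names : list of str
        Unique column names, length p.
    cell_ids : list of str
        Unique row identifiers, length n.
    """

    values: np.ndarray
    feature_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 2:
            raise ValueError(f"need n >= 1 cells and p >= 2 features, got {n} x {p}")
        self.feature_names = [str(f) for f in self.feature_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match matrix width")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match matrix height")
        _check_unique(self.feature_names, "feature names")
        _check_unique(self.cell_ids, "cell ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at cell {self.cell_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature: str) -> np.ndarray:
        try:
            j = self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"feature {feature!r} not present") from None
        return self.values[:, j]

    def select_features(self, features: list[str]) -> "CellMatrix":
        """Column subset in the requested order; missing names raise KeyError."""
        missing = [f for f in features if f not in self.feature_names]
        if missing:
            raise KeyError(f"features not present: {missing}")
        if len(features) < 2:
            raise ValueError("a CellMatrix needs at least 2 features")
        idx = [self.feature_names.index(f) for f in features]
        return CellMatrix(self.values[:, idx], list(features), list(self.cell_ids))

    def select_cells(self, indices: np.ndarray) -> "CellMatrix":
        indices = np.asarray(indices, dtype=int)
        return CellMatrix(
            self.values[indices],
            list(self.feature_names),
            [self.cell_ids[i] for i in indices],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CellMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_names)


@dataclass
class LabelVector:
    """Per-cell categorical class assignment.

    ``classes`` fixes the class order used for tie-breaking and, when
    ``cyclic`` is true, defines adjacency modulo k (phase i is adjacent to
    phases i-1 and i+1 around the circle).
    """

    labels: np.ndarray
    classes: list[str] = field(default_factory=list)
    cyclic: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(v) for v in np.asarray(self.labels).ravel()])
        if not self.classes:
            # default order: first appearance
            seen: dict[str, None] = {}
            for v in self.labels:
                seen.setdefault(v, None)
            self.classes = list(seen)
        else:
            self.classes = [str(c) for c in self.classes]
        _check_unique(self.classes, "classes")
        unknown = sorted(set(self.labels) - set(self.classes))
        if unknown:
            raise ValueError(f"labels not in declared classes: {unknown[:5]}")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def __len__(self) -> int:
        return len(self.labels)

    def codes(self) -> np.ndarray:
        """Integer code of each label in ``classes`` order."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.asarray([lut[v] for v in self.labels], dtype=int)

    def counts(self) -> np.ndarray:
        codes = self.codes()
        return np.bincount(codes, minlength=self.n_classes)

    def select(self, indices: np.ndarray) -> "LabelVector":
        indices = np.asarray(indices, dtype=int)
        return LabelVector(self.labels[indices], list(self.classes), self.cyclic)

    def is_adjacent(self, a: str, b: str) -> bool:
        """Whether two classes are neighbours; modulo k when cyclic."""
        ia, ib = self.classes.index(a), self.classes.index(b)
        d = abs(ia - ib)
        if self.cyclic:
            d = min(d, self.n_classes - d)
        return d == 1


@dataclass
class TransformSpec:
    """Mass-cytometry preprocessing parameters.

    arcsinh_cofactor : positive, default 5 (the CyTOF standard).
    quantile : in (0, 1], default 0.999; each feature is divided by its own
        empirical quantile at this level.
    clip : whether percentile normalization clips to [0, 1] afterwards.
    """

    arcsinh_cofactor: float = 5.0
    quantile: float = 0.999
    clip: bool = True

    def __post_init__(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh_cofactor must be positive")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")


@dataclass
class Embedding:
    """Per-cell coordinates on discriminant axes (LD1, LD2, ...)."""

    coords: np.ndarray
    cell_ids: list[str]
    axis_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")
        if not self.axis_names:
            self.axis_names = [f"LD{i + 1}" for i in range(self.coords.shape[1])]
        if len(self.axis_names) != self.coords.shape[1]:
            raise ValueError("axis_names length does not match coordinate columns")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match coordinate rows")

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def biaxial(self) -> np.ndarray:
        """First two axes as an (n, 2) array; a single axis is zero-padded.

        Separation metrics and the pixel grid are defined on the biaxial
        view; with k = 2 classes only one discriminant exists, so the second
        axis is a zero column.
        """
        if self.n_axes >= 2:
            return self.coords[:, :2]
        return np.column_stack([self.coords[:, 0], np.zeros(self.coords.shape[0])])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.cell_ids, columns=self.axis_names)
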