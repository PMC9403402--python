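"""Separation metrics scoring how well a biaxial embedding separates labels.

All metrics are evaluated on the first two embedding axes (the biaxial
visualization is what they judge).  Each is wrapped as a
:class:`SeparationMetric` with an explicit orientation so the subset search
can always maximize an oriented "goodness"; user metrics plug into the same
contract via the registry (``get_metric("custom:/path/to/metric.py")``).

Built-in metrics:

``euclidean``     minimum pairwise Euclidean distance between class means --
                  rewards only embeddings that separate *all* labels.
``silhouette``    mean silhouette coefficient (capped, seeded subsample above
                  5,000 cells to keep search loops tractable).
``pce``           pixel class entropy: 1 - entropy/log2(k) averaged over the
                  occupied pixels of a 100 x 100 grid; 1 = perfectly pure.
``pixeldensity``  mean per-pixel majority-class impurity on the same grid;
                  lower is better.
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics import silhouette_score as _sk_silhouette

from .containers import Embedding, LabelVector

__all__ = [
    "SeparationMetric",
    "PixelGrid",
    "min_centroid_distance",
    "silhouette_score",
    "pce_score",
    "pixel_density_score",
    "get_metric",
    "METRICS",
]

SILHOUETTE_CAP = 5000


@dataclass(frozen=True)
class SeparationMetric:
    """Named, oriented scoring contract used by the subset search."""

    name: str
    orientation: str  # "higher_is_better" | "lower_is_better"
    evaluate: Callable[[Embedding, LabelVector], float]

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_is_better", "lower_is_better"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def oriented(self, e: Embedding, y: LabelVector) -> float:
        """Score on a maximize-me scale regardless of orientation."""
        raw = self.evaluate(e, y)
        return raw if self.orientation == "higher_is_better" else -raw


@dataclass
class PixelGrid:
    """Per-pixel per-class cell counts on a bins_x x bins_y grid.

    Grid bounds are the exact data min/max per axis; bins are half-open with
    the maximum edge closed, so every cell lands in exactly one pixel.
    """

    counts: np.ndarray  # (bins_x, bins_y, k)
    bins_x: int
    bins_y: int

    @classmethod
    def from_embedding(
        cls, e: Embedding, y: LabelVector, bins_x: int = 100, bins_y: int = 100
    ) -> "PixelGrid":
        xy = e.biaxial()
        if xy.shape[0] == 0:
            raise ValueError("empty embedding")
        codes = y.codes()
        counts = np.zeros((bins_x, bins_y, y.n_classes), dtype=np.int64)
        ix = _bin_index(xy[:, 0], bins_x)
        iy = _bin_index(xy[:, 1], bins_y)
        np.add.at(counts, (ix, iy, codes), 1)
        return cls(counts=counts, bins_x=bins_x, bins_y=bins_y)

    def occupied(self) -> np.ndarray:
        """(m, k) class-count rows for the occupied pixels only."""
        flat = self.counts.reshape(-1, self.counts.shape[2])
        return flat[flat.sum(axis=1) > 0]


def _bin_index(v: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:  # degenerate axis: everything in the first bin
        return np.zeros(len(v), dtype=int)
    idx = np.floor((v - lo) / (hi - lo) * bins).astype(int)
    return np.clip(idx, 0, bins - 1)  # closes the max edge


def _class_means(e: Embedding, y: LabelVector) -> np.ndarray:
    xy = e.biaxial()
    codes = y.codes()
    counts = y.counts()
    if (counts == 0).any():
        empty = [y.classes[c] for c in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes with zero cells: {empty}")
    return np.vstack([xy[codes == c].mean(axis=0) for c in range(y.n_classes)])


def min_centroid_distance(e: Embedding, y: LabelVector) -> float:
    """Minimum pairwise Euclidean distance between class means (biaxial)."""
    means = _class_means(e, y)
    diff = means[:, None, :] - means[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(means), k=1)
    return float(d[iu].min())


def silhouette_score(
    e: Embedding, y: LabelVector, cap: int = SILHOUETTE_CAP, seed: int = 0
) -> float:
    """Mean silhouette coefficient on the biaxial view, in [-1, 1].

    Above ``cap`` cells a class-stratified, seeded subsample is scored
    instead (silhouette is O(n^2)); the draw guarantees >= 2 cells per class
    so no class degenerates to a singleton.
    """
    xy = e.biaxial()
    codes = y.codes()
    if len(xy) > cap:
        rng = np.random.default_rng(seed)
        picks = []
        counts = y.counts()
        # floor of 2 per class, remainder proportional
        floors = np.minimum(2, counts)
        budget = max(cap - int(floors.sum()), 0)
        avail = counts - floors
        extra = (
            np.floor(budget * avail / avail.sum()).astype(int)
            if avail.sum() > 0
            else np.zeros_like(avail)
        )
        for c in range(y.n_classes):
            idx = np.flatnonzero(codes == c)
            take = min(int(floors[c] + extra[c]), len(idx))
            picks.append(rng.choice(idx, size=take, replace=False))
        sel = np.sort(np.concatenate(picks))
        xy, codes = xy[sel], codes[sel]
    return float(_sk_silhouette(xy, codes, metric="euclidean"))


def pce_score(
    e: Embedding, y: LabelVector, bins_x: int = 100, bins_y: int = 100
) -> float:
    """Pixel class entropy score, in [0, 1]; 1 = every pixel is pure.

    The biaxial plot is pixelated into a ``bins_x x bins_y`` grid; each
    occupied pixel contributes ``1 - H(class proportions)/log2(k)`` where H
    is Shannon entropy in bits, and the score is the unweighted mean over
    occupied pixels (empty pixels carry no information).
    """
    if y.n_classes < 2:
        raise ValueError("PCE needs k >= 2 (log2(1) = 0)")
    rows = PixelGrid.from_embedding(e, y, bins_x, bins_y).occupied()
    pr = rows / rows.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(pr > 0, -pr * np.log2(pr), 0.0).sum(axis=1)
    return float(np.mean(1.0 - h / np.log2(y.n_classes)))


def pixel_density_score(
    e: Embedding, y: LabelVector, bins_x: int = 100, bins_y: int = 100
) -> float:
    """Mean per-pixel majority-class impurity; lower is better.

    Each occupied pixel contributes ``1 - max class proportion``; a pure
    pixel scores 0, a uniform k-way mix scores 1 - 1/k.
    """
    if y.n_classes < 2:
        raise ValueError("pixel density needs k >= 2")
    rows = PixelGrid.from_embedding(e, y, bins_x, bins_y).occupied()
    pr = rows / rows.sum(axis=1, keepdims=True)
    return float(np.mean(1.0 - pr.max(axis=1)))


METRICS: dict[str, SeparationMetric] = {
    "euclidean": SeparationMetric(
        "euclidean", "higher_is_better", min_centroid_distance
    ),
    "silhouette": SeparationMetric(
        "silhouette", "higher_is_better", silhouette_score
    ),
    "pce": SeparationMetric("pce", "higher_is_better", pce_score),
    "pixeldensity": SeparationMetric(
        "pixeldensity", "lower_is_better", pixel_density_score
    ),
}


def get_metric(name: str | SeparationMetric) -> SeparationMetric:
    """Resolve a metric by registry name, ``custom:<path>``, or pass-through.

    A custom metric file must define ``evaluate(embedding, labels) -> float``
    and may define ``ORIENTATION`` (default ``higher_is_better``).
    """
    if isinstance(name, SeparationMetric):
        return name
    if name in METRICS:
        return METRICS[name]
    if name.startswith("custom:"):
        path = name[len("custom:"):]
        spec = importlib.util.spec_from_file_location("hsslda_custom_metric", path)
        if spec is None or spec.loader is None:
            raise ValueError(f"cannot load custom metric from {path!r}")
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        if not hasattr(mod, "evaluate"):
            raise ValueError(f"custom metric {path!r} defines no evaluate()")
        orientation = getattr(mod, "ORIENTATION", "higher_is_better")
        return SeparationMetric(f"custom:{path}", orientation, mod.evaluate)
    raise KeyError(
        f"unknown metric {name!r}; choose from {sorted(METRICS)} or 'custom:<path>'"
    )
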