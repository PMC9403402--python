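"""Reading/writing cell matrices, CyTOF transforms, and stratified subsampling.

The on-disk contract is a CSV/TSV with a header row, cells as rows and
features as columns, with the cell identifier in the first column and an
optional categorical label column.  Mass-cytometry preprocessing follows the
standard recipe: arcsinh with cofactor 5, then per-feature division by the
0.999 quantile (order matters; arcsinh comes first).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import CellMatrix, LabelVector, TransformSpec

logger = logging.getLogger(__name__)

__all__ = [
    "load_matrix",
    "write_matrix",
    "arcsinh_transform",
    "percentile_normalize",
    "preprocess",
    "stratified_subsample",
]


def load_matrix(
    path,
    label_column: str | None = None,
    cyclic: bool = False,
) -> tuple[CellMatrix, LabelVector | None]:
    """Load a cells x features table from CSV/TSV.

    The first column is taken as the cell identifier.  All remaining columns
    except ``label_column`` must be numeric; any missing or non-numeric entry
    is an error naming the offending cell and feature.

    Returns the matrix and, when ``label_column`` is given, the extracted
    :class:`LabelVector` (classes ordered by first appearance).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise KeyError(f"label column {label_column!r} not found in {path}")
        labels = LabelVector(df[label_column].to_numpy(), cyclic=cyclic)
        df = df.drop(columns=[label_column])

    bad = df.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing value at cell {df.index[i]!r}, "
            f"feature {df.columns[j]!r} in {path}"
        )
    # numpy's str -> float64 conversion is correctly rounded (lossless
    # round-trip with the %.17g writer); pandas' fast parser is not
    values = df.to_numpy(dtype=float)
    m = CellMatrix(values, list(df.columns), list(df.index))
    return m, labels


def write_matrix(
    m: CellMatrix,
    path,
    labels: LabelVector | None = None,
    label_column: str = "label",
) -> None:
    """Write a matrix (and optional labels) as CSV, full double precision."""
    df = m.to_dataframe()
    if labels is not None:
        df = df.copy()
        df[label_column] = labels.labels
    df.to_csv(path, index_label="cell_id", float_format="%.17g")


def arcsinh_transform(m: CellMatrix, spec: TransformSpec | None = None) -> CellMatrix:
    """asinh(x / cofactor), elementwise; the CyTOF variance-stabiliser."""
    spec = spec or TransformSpec()
    return CellMatrix(
        np.arcsinh(m.values / spec.arcsinh_cofactor),
        list(m.feature_names),
        list(m.cell_ids),
    )


def percentile_normalize(m: CellMatrix, spec: TransformSpec | None = None) -> CellMatrix:
    """Divide each feature by its own empirical quantile, then clip to [0, 1].

    The quantile uses the linear-interpolation convention so results are
    bit-reproducible.  A feature whose quantile is <= 0 has no meaningful
    scale and raises.  Clipping is on by default (``spec.clip``); without it
    the handful of cells above the quantile keep values > 1.
    """
    spec = spec or TransformSpec()
    q = np.quantile(m.values, spec.quantile, axis=0, method="linear")
    nonpos = np.flatnonzero(q <= 0)
    if nonpos.size:
        names = [m.feature_names[j] for j in nonpos[:5]]
        raise ValueError(
            f"quantile {spec.quantile} is <= 0 for feature(s) {names}; "
            "cannot percentile-normalize"
        )
    out = m.values / q
    if spec.clip:
        out = np.clip(out, 0.0, 1.0)
    return CellMatrix(out, list(m.feature_names), list(m.cell_ids))


def preprocess(m: CellMatrix, spec: TransformSpec | None = None) -> CellMatrix:
    """Standard pipeline: arcsinh first, then percentile normalization."""
    spec = spec or TransformSpec()
    return percentile_normalize(arcsinh_transform(m, spec), spec)


def stratified_subsample(
    m: CellMatrix,
    y: LabelVector,
    target_n: int,
    min_per_class: int = 20,
    seed: int = 0,
) -> tuple[CellMatrix, LabelVector]:
    """Subsample without replacement, never dropping a class.

    Every class keeps a floor of ``min(min_per_class, class size)`` cells so
    rare populations survive; the remaining budget is allocated
    proportionally to class frequency (largest-remainder rounding).  If
    ``target_n`` cannot even cover the floors, a warning is issued and the
    floor-only sample is returned.  Deterministic given ``seed``.
    """
    if target_n < 1:
        raise ValueError("target_n must be positive")
    rng = np.random.default_rng(seed)
    codes = y.codes()
    sizes = y.counts()
    floors = np.minimum(min_per_class, sizes)

    if floors.sum() >= target_n:
        if floors.sum() > target_n:
            warnings.warn(
                f"target_n={target_n} below the per-class floors "
                f"(sum {int(floors.sum())}); returning the floor-only sample",
                stacklevel=2,
            )
        take = floors
    else:
        budget = target_n - int(floors.sum())
        avail = sizes - floors
        if avail.sum() <= budget:
            take = sizes.copy()
        else:
            ideal = budget * avail / avail.sum()
            take = floors + np.floor(ideal).astype(int)
            rem = budget - int(np.floor(ideal).sum())
            # largest fractional remainders get the leftover slots
            order = np.argsort(-(ideal - np.floor(ideal)), kind="stable")
            for c in order[:rem]:
                take[c] += 1
            take = np.minimum(take, sizes)

    chosen: list[np.ndarray] = []
    for c in range(y.n_classes):
        idx = np.flatnonzero(codes == c)
        chosen.append(rng.choice(idx, size=int(take[c]), replace=False))
    keep = np.sort(np.concatenate(chosen))
    return m.select_cells(keep), y.select(keep)
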