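"""Hybrid subset selection: stepwise search for the feature set that best
separates classes in the biaxial discriminant plot.

The search (a) fits LDA on every feature pair and keeps the best-scoring
pair, then (b) alternates forward steps (add the single best feature, even
when every addition worsens the score -- the walk must reach the full
feature set) and backward steps (drop the feature whose removal most
strictly improves the score, never the one just added, which guarantees
net growth and hence termination), until all p features are in play.
Every fit is recorded; the best score at each subset size from 2 to p forms
a curve whose elbow -- the point farthest from the chord joining its
endpoints, after min-max normalizing both axes -- picks the final subset
size, and the final model is refit on that subset.

Scores are compared with absolute tolerance 1e-12 and ties are broken
lexicographically by feature name, so the whole search is deterministic.
Fits that fail even with the ridge are recorded at -inf and skipped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellMatrix, LabelVector
from .lda import DiscriminantModel, fit_lda, transform
from .metrics import SeparationMetric, get_metric

logger = logging.getLogger(__name__)

__all__ = ["HSSTrace", "TraceEntry", "hss_select", "elbow_point"]

SCORE_TOL = 1e-12
MAX_FEATURES = 100
#: advisory cell-count range for running the search (subsample above it)
ADVISORY_CELLS = (50_000, 200_000)


@dataclass(frozen=True)
class TraceEntry:
    features: tuple[str, ...]  # sorted
    raw_score: float
    oriented_score: float
    failed: bool = False

    @property
    def size(self) -> int:
        return len(self.features)


@dataclass
class HSSTrace:
    """Full audit record of a subset search."""

    metric_name: str
    evaluated: list[TraceEntry] = field(default_factory=list)
    best_per_size: dict[int, TraceEntry] = field(default_factory=dict)
    elbow_size: int = 0
    final_features: list[str] = field(default_factory=list)
    n_fits: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size": e.size,
                "features": "|".join(e.features),
                "raw_score": e.raw_score,
                "oriented_score": e.oriented_score,
                "selected": list(e.features) == sorted(self.final_features),
            }
            for e in self.evaluated
        ]
        return pd.DataFrame(rows)

    def size_curve(self) -> tuple[list[int], list[float]]:
        sizes = sorted(self.best_per_size)
        return sizes, [self.best_per_size[s].oriented_score for s in sizes]


class _Scorer:
    """Caches LDA fits per subset; every candidate evaluation is traced."""

    def __init__(
        self, m: CellMatrix, y: LabelVector, metric: SeparationMetric, trace: HSSTrace
    ):
        self.m, self.y, self.metric, self.trace = m, y, metric, trace
        self._cache: dict[tuple[str, ...], TraceEntry] = {}

    def score(self, features: tuple[str, ...]) -> TraceEntry:
        key = tuple(sorted(features))
        entry = self._cache.get(key)
        if entry is None:
            try:
                model = fit_lda(self.m, self.y, features=list(key))
                emb = transform(model, self.m)
                raw = self.metric.evaluate(emb, self.y)
                oriented = (
                    raw
                    if self.metric.orientation == "higher_is_better"
                    else -raw
                )
                if not np.isfinite(oriented):
                    raise ValueError(f"metric returned non-finite score {raw}")
                entry = TraceEntry(key, raw, oriented)
            except Exception as exc:  # irrecoverable fit: score -inf, skip
                logger.warning("fit failed for %s: %s", key, exc)
                entry = TraceEntry(key, float("nan"), float("-inf"), failed=True)
            self._cache[key] = entry
            self.trace.n_fits += 1
        self.trace.evaluated.append(entry)
        if not entry.failed:
            best = self.trace.best_per_size.get(entry.size)
            if (
                best is None
                or entry.oriented_score > best.oriented_score + SCORE_TOL
                or (
                    abs(entry.oriented_score - best.oriented_score) <= SCORE_TOL
                    and entry.features < best.features
                )
            ):
                self.trace.best_per_size[entry.size] = entry
        return entry


def _best(entries: list[TraceEntry]) -> TraceEntry:
    """Max oriented score; ties within tolerance go to the lexicographically
    smallest feature tuple."""
    best = entries[0]
    for e in entries[1:]:
        if e.oriented_score > best.oriented_score + SCORE_TOL:
            best = e
        elif (
            abs(e.oriented_score - best.oriented_score) <= SCORE_TOL
            and e.features < best.features
        ):
            best = e
    return best


def _initialize_pair(scorer: _Scorer, features: list[str]) -> TraceEntry:
    entries = [
        scorer.score(pair)
        for pair in itertools.combinations(sorted(features), 2)
    ]
    ok = [e for e in entries if not e.failed]
    if not ok:
        raise RuntimeError("every feature pair failed to fit; cannot initialize")
    return _best(ok)


def _forward_step(
    scorer: _Scorer, current: tuple[str, ...], remaining: list[str]
) -> tuple[tuple[str, ...], str, TraceEntry]:
    """Add the single best feature (unconditionally -- the walk must grow)."""
    cands = []
    for f in sorted(remaining):
        entry = scorer.score(current + (f,))
        cands.append((f, entry))
    ok = [(f, e) for f, e in cands if not e.failed] or cands
    best_f, best_e = ok[0]
    for f, e in ok[1:]:
        if e.oriented_score > best_e.oriented_score + SCORE_TOL:
            best_f, best_e = f, e
        elif (
            abs(e.oriented_score - best_e.oriented_score) <= SCORE_TOL
            and e.features < best_e.features
        ):
            best_f, best_e = f, e
    return best_e.features, best_f, best_e


def _backward_step(
    scorer: _Scorer,
    current: tuple[str, ...],
    current_score: float,
    just_added: str,
) -> tuple[tuple[str, ...], float, bool]:
    """Drop the feature whose removal most strictly improves the score.

    The feature just added by the forward step is exempt (termination
    guard); removal below 2 features is never attempted.
    """
    if len(current) < 3:
        return current, current_score, False
    cands = []
    for f in current:
        if f == just_added:
            continue
        reduced = tuple(sorted(set(current) - {f}))
        cands.append(scorer.score(reduced))
    ok = [e for e in cands if not e.failed]
    if not ok:
        return current, current_score, False
    best = _best(ok)
    if best.oriented_score > current_score + SCORE_TOL:
        return best.features, best.oriented_score, True
    return current, current_score, False


def elbow_point(
    sizes: list[int], scores: list[float], normalize: bool = True
) -> int:
    """Subset size at the elbow of the best-score-per-size curve.

    The elbow is the point farthest (perpendicular distance) from the chord
    joining the first and last points.  Because subset size and score are in
    incommensurable units, both axes are min-max normalized to [0, 1] first
    (``normalize=False`` disables this).  Ties -- including fully collinear
    curves -- resolve to the smaller size; with exactly 2 points the smaller
    size is returned.
    """
    if len(sizes) != len(scores):
        raise ValueError("sizes and scores must be the same length")
    if len(sizes) < 2:
        raise ValueError("need at least 2 points")
    s = np.asarray(sizes, dtype=float)
    if not np.all(np.diff(s) > 0):
        raise ValueError("sizes must be strictly increasing")
    v = np.asarray(scores, dtype=float)
    if len(s) == 2:
        return int(sizes[0])
    if normalize:
        s = (s - s[0]) / (s[-1] - s[0])
        rng = v.max() - v.min()
        v = (v - v.min()) / rng if rng > 0 else np.zeros_like(v)
    dx, dy = s[-1] - s[0], v[-1] - v[0]
    # |cross| / chord length; chord length is a common factor, skip it
    dist = np.abs((s - s[0]) * dy - (v - v[0]) * dx)
    best = 0
    for i in range(1, len(dist)):
        if dist[i] > dist[best] + SCORE_TOL:
            best = i
    return int(sizes[best])


def hss_select(
    m: CellMatrix,
    y: LabelVector,
    metric: str | SeparationMetric = "euclidean",
    features: list[str] | None = None,
    allow_large: bool = False,
    normalize_elbow: bool = True,
) -> tuple[DiscriminantModel, HSSTrace]:
    """Run hybrid subset selection and return the elbow-selected final model.

    Parameters
    ----------
    m, y : training matrix and labels.
    metric : registry name, ``custom:<path>``, or a
        :class:`~hsslda.metrics.SeparationMetric`.
    features : optional pool of candidate features (default: all columns).
    allow_large : the search fits O(p^2) models per sweep and is refused
        above 100 features unless this is set.
    normalize_elbow : min-max normalize the elbow axes (default on).
    """
    pool = sorted(features) if features is not None else sorted(m.feature_names)
    p = len(pool)
    if p < 2:
        raise ValueError("need at least 2 candidate features")
    if p > MAX_FEATURES and not allow_large:
        raise ValueError(
            f"{p} features exceeds the {MAX_FEATURES}-feature practicality limit "
            "for stepwise search; pass allow_large=True to override"
        )
    if not ADVISORY_CELLS[0] <= m.n_cells <= ADVISORY_CELLS[1]:
        logger.info(
            "subset search on %d cells (advisory working range %d-%d; "
            "stratified subsampling keeps the search fast on larger data)",
            m.n_cells, *ADVISORY_CELLS,
        )

    metric = get_metric(metric)
    trace = HSSTrace(metric_name=metric.name)
    scorer = _Scorer(m, y, metric, trace)

    best_pair = _initialize_pair(scorer, pool)
    current, score = best_pair.features, best_pair.oriented_score

    iterations = 0
    max_iterations = 2 * p
    while len(current) < p:
        remaining = [f for f in pool if f not in current]
        current, added, entry = _forward_step(scorer, current, remaining)
        score = entry.oriented_score
        iterations += 1
        if iterations <= max_iterations:
            current, score, _removed = _backward_step(scorer, current, score, added)

    sizes, curve = trace.size_curve()
    if len(sizes) == 1:  # p == 2: nothing to select
        trace.elbow_size = sizes[0]
    else:
        trace.elbow_size = elbow_point(sizes, curve, normalize=normalize_elbow)
    trace.final_features = list(trace.best_per_size[trace.elbow_size].features)
    model = fit_lda(m, y, features=trace.final_features)
    return model, trace
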