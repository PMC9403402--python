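"""Seed-deterministic synthetic datasets with the statistical structure each
analysis assumes.

Three generators cover the three supervised settings the method addresses:

* :func:`make_blobs` -- discrete, possibly imbalanced Gaussian class
  mixtures with informative plus pure-noise features (cell-type panels);
* :func:`make_trajectory` -- ordinal classes whose means march along one
  latent direction (activation/differentiation time courses);
* :func:`make_cycle` -- a circular 5-phase score matrix in which each
  phase score is a smooth unimodal bump of the cell's true angle, so
  adjacent phases correlate positively and non-adjacent phases
  anti-correlate, and the class label is the arg-max score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CellMatrix, LabelVector

__all__ = ["BlobSpec", "CycleSpec", "make_blobs", "make_trajectory", "make_cycle"]

CYCLE_PHASES = ["G1.S", "S", "G2", "G2.M", "M.G1"]


@dataclass
class BlobSpec:
    """Discrete Gaussian-mixture design.

    separation is the pairwise distance between class centroids in units of
    the within-class standard deviation (1.0); noise features share one
    distribution across classes and carry no signal.
    """

    k: int = 3
    p_informative: int = 2
    p_noise: int = 4
    class_sizes: list[int] = field(default_factory=list)
    separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.p_informative < 1 or self.p_noise < 0:
            raise ValueError("counts must be positive (k >= 2)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not self.class_sizes:
            self.class_sizes = [100] * self.k
        if len(self.class_sizes) != self.k:
            raise ValueError("class_sizes length must equal k")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")


@dataclass
class CycleSpec:
    """Circular phase-score design (defaults emulate 5-phase cell cycle)."""

    phases: list[str] = field(default_factory=lambda: list(CYCLE_PHASES))
    n: int = 2000
    concentration: float = 0.0  # von Mises kappa; 0 = uniform angles
    score_noise_sd: float = 0.1  # bump amplitude is 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phases) < 3:
            raise ValueError("need at least 3 phases")
        if self.concentration < 0 or self.score_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n < len(self.phases):
            raise ValueError("need at least one cell per phase")


def _class_means(k: int, p: int, separation: float, rng) -> np.ndarray:
    """k centroids with minimum pairwise distance exactly ``separation``.

    k <= p: a regular simplex (every pair at distance ``separation``);
    p >= 2 otherwise: a regular k-gon whose adjacent vertices are
    ``separation`` apart; p == 1: an evenly spaced line.  A random rotation
    is applied so the informative directions are not axis-aligned.
    """
    if k <= p:
        means = np.zeros((k, p))
        means[:, :k] = (separation / np.sqrt(2.0)) * np.eye(k)
    elif p >= 2:
        radius = separation / (2.0 * np.sin(np.pi / k))
        ang = 2.0 * np.pi * np.arange(k) / k
        means = np.zeros((k, p))
        means[:, 0] = radius * np.cos(ang)
        means[:, 1] = radius * np.sin(ang)
    else:
        means = separation * np.arange(k, dtype=float)[:, None]
    rot, _ = np.linalg.qr(rng.normal(size=(p, p)))
    return (means - means.mean(axis=0)) @ rot.T


def make_blobs(spec: BlobSpec) -> tuple[CellMatrix, LabelVector]:
    """Gaussian classes differing only on the informative features."""
    rng = np.random.default_rng(spec.seed)
    means = _class_means(spec.k, spec.p_informative, spec.separation, rng)
    n = int(sum(spec.class_sizes))
    labels = np.repeat([f"class_{i + 1}" for i in range(spec.k)], spec.class_sizes)
    inf = rng.normal(size=(n, spec.p_informative))
    inf += np.repeat(means, spec.class_sizes, axis=0)
    noise = rng.normal(size=(n, spec.p_noise))
    values = np.hstack([inf, noise])
    names = [f"inf_{j + 1}" for j in range(spec.p_informative)] + [
        f"noise_{j + 1}" for j in range(spec.p_noise)
    ]
    ids = [f"cell_{i:05d}" for i in range(n)]
    y = LabelVector(labels, [f"class_{i + 1}" for i in range(spec.k)])
    return CellMatrix(values, names, ids), y


def make_trajectory(
    k: int = 5,
    n_per_class: int = 200,
    drift: float = 3.0,
    p_noise: int = 3,
    seed: int = 0,
    drift_scale: float = 1.0,
) -> tuple[CellMatrix, LabelVector]:
    """Ordinal classes marching along one latent direction.

    Class t (t = 0..k-1) has mean ``t * drift * drift_scale * u`` on the 3
    informative features, for a fixed unit direction u; ``drift_scale < 1``
    produces a "stunted" cohort whose late classes sit where an earlier
    class of the reference cohort would (held-out projection fixture).
    """
    if k < 3:
        raise ValueError("need k >= 3 time points")
    rng = np.random.default_rng(seed)
    p_inf = 3
    u = rng.normal(size=p_inf)
    u /= np.linalg.norm(u)
    n = k * n_per_class
    t = np.repeat(np.arange(k), n_per_class)
    inf = rng.normal(size=(n, p_inf)) + np.outer(t * drift * drift_scale, u)
    noise = rng.normal(size=(n, p_noise))
    names = [f"inf_{j + 1}" for j in range(p_inf)] + [
        f"noise_{j + 1}" for j in range(p_noise)
    ]
    ids = [f"cell_{i:05d}" for i in range(n)]
    y = LabelVector(
        [f"t{v + 1}" for v in t], [f"t{v + 1}" for v in range(k)]
    )
    return CellMatrix(np.hstack([inf, noise]), names, ids), y


def _circular_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def phase_score_profile(d: np.ndarray, phase_width: float) -> np.ndarray:
    """Raised-cosine bump with compact support of +/- 2 phase widths.

    d is circular distance in degrees from the phase centre.  The profile is
    smooth, unimodal and overlaps its neighbours, which is what yields the
    positive adjacent-phase and negative opposite-phase score correlations
    characteristic of real cell-cycle scores.
    """
    half = 2.0 * phase_width
    return np.where(d <= half, 0.5 * (1.0 + np.cos(np.pi * d / half)), 0.0)


def make_cycle(spec: CycleSpec) -> tuple[CellMatrix, LabelVector, np.ndarray]:
    """Circular phase-score matrix; returns (scores, labels, true_angle).

    Each cell gets a true angle theta on [0, 360): uniform when
    ``concentration == 0``, else a balanced von Mises mixture around the k
    equally spaced phase centres.  Phase j's score is the raised-cosine bump
    of the circular distance from theta to centre j, plus Gaussian noise;
    the label is the arg-max score, so at zero noise every label is the
    phase nearest the true angle and at moderate noise confusion lives on
    phase boundaries (transitional cells).
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.phases)
    width = 360.0 / k
    centers = np.arange(k) * width

    if spec.concentration == 0:
        theta = rng.uniform(0.0, 360.0, size=spec.n)
    else:
        which = rng.integers(k, size=spec.n)
        theta = (
            np.degrees(rng.vonmises(0.0, spec.concentration, size=spec.n))
            + centers[which]
        ) % 360.0

    scores = np.column_stack(
        [phase_score_profile(_circular_distance(theta, c), width) for c in centers]
    )
    scores = scores + rng.normal(scale=spec.score_noise_sd, size=scores.shape)
    labels = np.asarray(spec.phases)[np.argmax(scores, axis=1)]
    ids = [f"cell_{i:05d}" for i in range(spec.n)]
    m = CellMatrix(scores, list(spec.phases), ids)
    y = LabelVector(labels, list(spec.phases), cyclic=True)
    return m, y, theta
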