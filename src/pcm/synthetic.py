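"""Synthetic patient matrices with planted cluster structure.

Each planted group models a distinct disease profile: a group's centroid
is elevated on its own block of "signature" indicators and zero
elsewhere, so distinct centroids have disjoint supports and pairwise
angles of 90 degrees — the widest separation nonnegative health data
admit, since two nonnegative vectors can never be more than orthogonal.
Patients are their group centroid plus i.i.d. Gaussian noise, clipped
at zero, with cells masked missing uniformly at random.  Angular (not
Euclidean) separation is the difficulty knob because sign-of-projection
hashing is scale-invariant.

Emulates a matrix-structured benchmark with known ground truth; it does
not attempt to match any real clinical marginal distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import PatientHealthMatrix

_MAX_CENTROID_RETRIES = 20


class GenerationError(RuntimeError):
    """Requested angular separation could not be achieved."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted-cluster generator settings.

    m, n : patients and diseases (defaults follow the evaluation scale
        of 300 patients by 5000 indicators).
    g : number of planted groups.
    group_sizes : per-group patient counts summing to m; None = as even
        a split as possible.
    centroid_scale : typical magnitude of a signature indicator
        (arbitrary health-monitoring units).
    noise_sd : per-entry Gaussian noise standard deviation, same units.
    min_centroid_angle : required minimum pairwise centroid angle,
        radians; values above pi/2 are infeasible for nonnegative data.
    missing_rate : probability a cell is masked unobserved.
    """

    m: int = 300
    n: int = 5000
    g: int = 4
    group_sizes: tuple[int, ...] | None = None
    centroid_scale: float = 10.0
    noise_sd: float = 0.5
    min_centroid_angle: float = math.pi / 3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.g < 1:
            raise ValueError("m, n and g must be positive")
        if self.g > self.m:
            raise ValueError("cannot plant more groups than patients")
        if self.g > self.n:
            raise ValueError("need at least one signature indicator per group")
        if self.group_sizes is not None:
            sizes = tuple(int(s) for s in self.group_sizes)
            if len(sizes) != self.g or sum(sizes) != self.m or min(sizes) < 1:
                raise ValueError("group_sizes must be g positive counts summing to m")
            object.__setattr__(self, "group_sizes", sizes)
        if self.centroid_scale <= 0:
            raise ValueError("centroid_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.min_centroid_angle <= math.pi:
            raise ValueError("min_centroid_angle must lie in [0, pi]")

    def resolved_group_sizes(self) -> tuple[int, ...]:
        if self.group_sizes is not None:
            return self.group_sizes
        base, extra = divmod(self.m, self.g)
        return tuple(base + (1 if i < extra else 0) for i in range(self.g))


def _pairwise_angles(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1)
    cos = (vectors @ vectors.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    return np.arccos(cos)


def _draw_centroids(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Disjoint-support centroids with verified angular separation."""
    for _ in range(_MAX_CENTROID_RETRIES):
        centroids = np.zeros((spec.g, spec.n))
        perm = rng.permutation(spec.n)
        block = spec.n // spec.g
        for gi in range(spec.g):
            support = perm[gi * block : (gi + 1) * block] if spec.g > 1 else perm
            if len(support) == 0:  # n < g is rejected earlier; guard anyway
                raise GenerationError("empty signature block")
            centroids[gi, support] = spec.centroid_scale * rng.uniform(
                0.5, 1.5, size=len(support)
            )
        if spec.g == 1:
            return centroids
        angles = _pairwise_angles(centroids)
        off = angles[np.triu_indices(spec.g, k=1)]
        if np.all(off >= spec.min_centroid_angle - 1e-9):
            return centroids
    raise GenerationError(
        f"could not draw {spec.g} nonnegative centroids with pairwise angle >= "
        f"{spec.min_centroid_angle:.3f} rad in {_MAX_CENTROID_RETRIES} attempts "
        "(nonnegative vectors cannot exceed pi/2)"
    )


def generate(spec: SyntheticSpec) -> tuple[PatientHealthMatrix, np.ndarray]:
    """Generate a planted-cluster matrix and its ground-truth labels.

    Deterministic per ``spec.seed``.  Returns the matrix (with
    ``missing_rate`` of cells masked) and an integer label array of
    length m giving each patient's planted group.
    """
    rng = np.random.default_rng(spec.seed)
    centroids = _draw_centroids(spec, rng)
    sizes = spec.resolved_group_sizes()
    labels = np.repeat(np.arange(spec.g), sizes)
    values = centroids[labels] + spec.noise_sd * rng.standard_normal((spec.m, spec.n))
    np.clip(values, 0.0, None, out=values)
    observed = np.ones((spec.m, spec.n), dtype=bool)
    if spec.missing_rate > 0:
        observed = rng.random((spec.m, spec.n)) >= spec.missing_rate
    values = np.where(observed, values, np.nan)
    matrix = PatientHealthMatrix(
        patient_ids=[f"p{i + 1}" for i in range(spec.m)],
        disease_ids=[f"d{j + 1}" for j in range(spec.n)],
        values=values,
        observed_mask=observed,
    )
    return matrix, labels


def angle_stats(matrix: PatientHealthMatrix, labels: np.ndarray) -> tuple[float, float]:
    """(mean within-group angle, mean between-group angle), radians.

    Certifies a fixture's separability before clustering tests lean on
    it.  Missing entries are treated as zero, matching the default
    policy the hash applies.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("angle_stats needs at least two groups")
    X = matrix.resolved_values("zero")
    angles = _pairwise_angles(X)
    iu = np.triu_indices(matrix.m, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    return float(angles[iu][same].mean()), float(angles[iu][~same].mean())
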