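"""Odor-coding similarity analyses.

Within each animal, the neural representation of an odorant is its
presentation-averaged response map; representational dissimilarity
between two odorants is the pixel-wise Euclidean distance

    d(o1, o2) = sqrt( sum_{x,y in mask} (I_o1(x,y) - I_o2(x,y))^2 )

over all in-mask pixels.  For the 16-odorant aliphatic panel this gives
120 unordered odor pairs per bee.  Cross-bee mean matrices feed Ward
hierarchical clustering and Mantel permutation tests against other
neural or behavioral distance matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy

from .types import Dendrogram, DistanceMatrix, ResponseMap, ValidationError


def euclidean_distance(
    map_a: ResponseMap, map_b: ResponseMap, squared: bool = False
) -> float:
    """Pixel-wise Euclidean distance between two response maps.

    ``squared=True`` skips the square root (a sensitivity-check mode;
    the standard measure is the plain Euclidean distance).
    """
    if map_a.amplitude.shape != map_b.amplitude.shape or not np.array_equal(
        map_a.mask.include, map_b.mask.include
    ):
        raise ValidationError("response maps have mismatched shapes or masks")
    diff = map_a.valid_values - map_b.valid_values
    ss = float((diff**2).sum())
    return ss if squared else math.sqrt(ss)


def pairwise_distances(
    maps: list[ResponseMap], squared: bool = False
) -> DistanceMatrix:
    """All-pairs Euclidean distance matrix for one bee's stimulus maps."""
    if len(maps) < 2:
        raise ValidationError("need at least 2 maps for pairwise distances")
    labels = [m.stimulus_id for m in maps]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate stimulus labels: {labels}")
    n = len(maps)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = euclidean_distance(
                maps[i], maps[j], squared=squared
            )
    return DistanceMatrix(values, labels, provenance="per-bee")


def mean_distance_matrix(
    matrices: list[DistanceMatrix],
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Entrywise mean and SEM of per-bee distance matrices."""
    if not matrices:
        raise ValidationError("no matrices to average")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValidationError("distance matrices have mismatched labels")
    stack = np.stack([m.values for m in matrices])
    mean = stack.mean(axis=0)
    if len(matrices) > 1:
        sem = stack.std(axis=0, ddof=1) / math.sqrt(len(matrices))
    else:
        sem = np.zeros_like(mean)
    np.fill_diagonal(sem, 0.0)
    return (
        DistanceMatrix(mean, labels, provenance="cross-bee-mean"),
        DistanceMatrix(sem, labels, provenance="cross-bee-sem"),
    )


@dataclass
class SameDifferentResult:
    """Per-bee same- vs different-odor distances and their paired t-test."""

    bee_ids: list[str]
    same_mean: np.ndarray  # per-bee mean distance, presentation 1 vs 2
    different_mean: np.ndarray  # per-bee mean over cross-odorant pairs
    t: float
    df: int
    p: float


def same_vs_different(
    per_presentation: dict, exclude_controls: tuple[str, ...] = ()
) -> SameDifferentResult:
    """Compare map distances within vs between odorants.

    ``per_presentation`` maps ``(bee_id, stimulus, presentation)`` to a
    :class:`ResponseMap`; exactly presentations 1 and 2 are required for
    every stimulus.  Per bee, the same-odor distance averages
    d(presentation 1, presentation 2) over stimuli, and the
    different-odor distance averages over all cross-odorant presentation
    pairs.  A paired t-test across bees compares the two per-bee means.
    """
    bees = sorted({k[0] for k in per_presentation})
    stimuli = sorted(
        {k[1] for k in per_presentation} - set(exclude_controls)
    )
    same_means, diff_means = [], []
    for bee in bees:
        for s in stimuli:
            for p in (1, 2):
                if (bee, s, p) not in per_presentation:
                    raise ValidationError(
                        f"missing presentation {p} of {s!r} for bee {bee!r}"
                    )
        same = [
            euclidean_distance(
                per_presentation[(bee, s, 1)], per_presentation[(bee, s, 2)]
            )
            for s in stimuli
        ]
        diff = [
            euclidean_distance(
                per_presentation[(bee, s1, p1)], per_presentation[(bee, s2, p2)]
            )
            for i, s1 in enumerate(stimuli)
            for s2 in stimuli[i + 1 :]
            for p1 in (1, 2)
            for p2 in (1, 2)
        ]
        same_means.append(float(np.mean(same)))
        diff_means.append(float(np.mean(diff)))
    same_arr = np.array(same_means)
    diff_arr = np.array(diff_means)
    t, p = sps.ttest_rel(same_arr, diff_arr)
    return SameDifferentResult(
        bees, same_arr, diff_arr, float(t), len(bees) - 1, float(p)
    )


def ward_clustering(distances: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering under the Ward criterion (Ward.D2).

    Operates on the Euclidean distance matrix via the Lance-Williams
    update on squared distances; merge heights are nondecreasing for any
    metric input.
    """
    if distances.n < 2:
        raise ValidationError("clustering needs at least 2 items")
    linkage = hierarchy.linkage(distances.condensed(), method="ward")
    return Dendrogram(linkage, list(distances.labels))


@dataclass
class MantelResult:
    """Mantel permutation test between two distance matrices."""

    r: float
    r_squared: float
    p: float
    n_permutations: int
    exhaustive: bool = False


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = 0,
    exhaustive_cap: int = 40320,  # 8!
) -> MantelResult:
    """Permutation test for correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; the null
    distribution jointly permutes rows and columns of ``d2``.  The
    two-sided p-value is ``(#{|r_perm| >= |r_obs|} + 1) / (B + 1)`` for
    Monte-Carlo sampling, or the exact fraction over all n! relabelings
    when n! does not exceed ``exhaustive_cap``.
    """
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices have mismatched labels")
    n = d1.n
    x = d1.condensed()
    if x.std() == 0:
        raise ValidationError("first matrix has zero off-diagonal variance")
    if d2.condensed().std() == 0:
        raise ValidationError("second matrix has zero off-diagonal variance")

    iu = np.triu_indices(n, k=1)
    xz = (x - x.mean()) / x.std()

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        sd = y.std()
        if sd == 0:
            return 0.0
        return float((xz * (y - y.mean()) / sd).mean())

    r_obs = corr(d2.values)
    if math.factorial(n) <= exhaustive_cap:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            if abs(corr(d2.values[np.ix_(idx, idx)])) >= abs(r_obs) - 1e-12:
                count += 1
            total += 1
        p = count / total
        n_used = total
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            idx = rng.permutation(n)
            if abs(corr(d2.values[np.ix_(idx, idx)])) >= abs(r_obs) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        n_used = n_permutations
        exhaustive = False
    return MantelResult(r_obs, r_obs**2, p, n_used, exhaustive)
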