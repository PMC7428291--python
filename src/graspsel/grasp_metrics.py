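"""Grasp similarity and behavioral statistics.

Similarity between two grasps is 100 * (1 - d6 / d_max), where d6 is the
Euclidean distance between the 6D grasp vectors and d_max the largest
pairwise distance between two points on the object.  Because d6 is taken
in 6D, it can exceed d_max, so similarity can be negative; values are
reported unclamped by default (``floor_at_zero`` clamps to 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, squareform, pdist

from graspsel.grasp_manifold import Grasp, grasp_vectors
from graspsel.object_model import CandidateSet, RigidObject, RigidTransform


@dataclass(frozen=True)
class SimilarityResult:
    value: float  # percent
    d6: float  # mm, 6D grasp distance
    d_max: float  # mm


def grasp_similarity(
    g1: Grasp, g2: Grasp, d_max: float, floor_at_zero: bool = False
) -> SimilarityResult:
    """Similarity (percent) between two grasps in a common frame."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    d6 = float(np.linalg.norm(g1.vector - g2.vector))
    value = 100.0 * (1.0 - d6 / d_max)
    if floor_at_zero:
        value = max(value, 0.0)
    return SimilarityResult(value, d6, float(d_max))


def medoid(grasps) -> Grasp:
    """Member minimizing the summed 6D distance to the other members.

    Ties break toward the lowest trial index (argmin order).
    """
    grasps = list(grasps)
    if not grasps:
        raise ValueError("need at least one grasp")
    if len(grasps) == 1:
        return grasps[0]
    v = grasp_vectors(grasps)
    dist = squareform(pdist(v))
    return grasps[int(dist.sum(axis=1).argmin())]


def mean_similarity_to_medoid(grasps, d_max: float) -> float:
    """Mean similarity of a grasp set to its own medoid (percent)."""
    m = medoid(grasps)
    return float(
        np.mean([grasp_similarity(g, m, d_max).value for g in grasps])
    )


def within_between_similarity(grasps_by_subject: dict, d_max: float) -> dict:
    """Within- and between-subject similarity per subject (percent).

    Within: mean similarity of each subject's grasps to their own medoid.
    Between: each subject's medoid vs the medoid of all other subjects'
    pooled grasps (requires >= 2 subjects).
    """
    subjects = list(grasps_by_subject)
    if not subjects:
        raise ValueError("no subjects")
    within = {
        s: mean_similarity_to_medoid(grasps_by_subject[s], d_max) for s in subjects
    }
    between = {}
    if len(subjects) >= 2:
        for s in subjects:
            own = medoid(grasps_by_subject[s])
            others = [g for o in subjects if o != s for g in grasps_by_subject[o]]
            between[s] = grasp_similarity(own, medoid(others), d_max).value
    return {"within": within, "between": between}


def random_grasps(cands: CandidateSet, n: int, rng) -> list[Grasp]:
    """Uniform random ordered candidate pairs (diagonal excluded)."""
    if cands.n < 2:
        raise ValueError("need at least 2 candidates")
    ti = rng.integers(0, cands.n, size=n)
    ii = rng.integers(0, cands.n - 1, size=n)
    ii = np.where(ii >= ti, ii + 1, ii)  # skip the diagonal uniformly
    return [
        Grasp(cands.positions[a], cands.positions[b],
              thumb_idx=int(a), index_idx=int(b))
        for a, b in zip(ti, ii)
    ]


def random_grasp_baseline(
    cands: CandidateSet,
    n: int,
    d_max: float,
    seed=None,
    n_boot: int = 1000,
) -> dict:
    """Chance-level grasp similarity due to object geometry alone.

    Samples ``n`` uniform random grasps, reports their mean similarity
    to their medoid, with a seeded bootstrap CI (2.5/97.5 percentiles).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample = random_grasps(cands, n, rng)
    value = mean_similarity_to_medoid(sample, d_max)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = mean_similarity_to_medoid([sample[i] for i in idx], d_max)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"value": value, "ci": (float(lo), float(hi)), "n": n}


def _midpoint_com_distances(grasps, com: np.ndarray) -> np.ndarray:
    mids = np.array([g.midpoint for g in grasps])
    return np.linalg.norm(mids - com, axis=1)


def com_attraction(
    grasps,
    obj: RigidObject,
    cands: CandidateSet,
    baseline_n: int = 1000,
    seed=None,
) -> float:
    """How much closer to the CoM observed grasps are than random ones (mm).

    Distance of a grasp to the CoM is taken from the thumb-index
    midpoint; positive values mean the observed grasps cluster nearer
    the CoM than uniform random candidate pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    com = obj.com
    observed = _midpoint_com_distances(grasps, com).mean()
    baseline = _midpoint_com_distances(
        random_grasps(cands, baseline_n, rng), com
    ).mean()
    return float(baseline - observed)


def spatial_bias(
    grasps, obj: RigidObject, start_point, planar: bool = False
) -> float:
    """How much closer to the hand start the grasps are than the object
    centroid (mm); positive = grasps biased toward the start location.

    ``planar`` measures distances in the horizontal x-y plane only.
    """
    start = np.asarray(start_point, dtype=float).reshape(3)
    centroid = obj.centroid
    mids = np.array([g.midpoint for g in grasps])
    if planar:
        start, centroid, mids = start[:2], centroid[:2], mids[:, :2]
    d_centroid = float(np.linalg.norm(start - centroid))
    d_grasps = float(np.linalg.norm(mids - start, axis=1).mean())
    return d_centroid - d_grasps


def encode_frame(grasp: Grasp, pose: RigidTransform, mode: str) -> Grasp:
    """Re-express a grasp for cross-orientation comparison.

    ``egocentric``: unchanged (observer-fixed participant frame).
    ``allocentric``: contacts mapped through the inverse object pose into
    the object-fixed frame, so grasps on differently posed presentations
    of the same object become directly comparable.
    """
    if mode == "egocentric":
        return grasp
    if mode == "allocentric":
        return grasp.transformed(pose.inverse())
    raise ValueError("mode must be 'egocentric' or 'allocentric'")


def nearest_candidate_distance(points: np.ndarray, cands: CandidateSet) -> np.ndarray:
    """Convenience: distance of arbitrary points to the candidate set."""
    return cdist(np.atleast_2d(points), cands.positions).min(axis=1)
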