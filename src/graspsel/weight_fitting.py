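"""Bounded least-squares fitting of constraint weights to observed grasps.

The observed grasps define a binary target penalty (0 at selected pairs,
1 elsewhere) and a regularization table that balances the few selected
pairs against the vast non-selected region; a trust-region-reflective
solver then finds the [0, 1]-bounded weights whose combined penalty best
approximates the target.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from graspsel.grasp_manifold import Grasp, sample_optimal_grasps
from graspsel.penalty_maps import PENALTY_LABELS, PenaltyMap, combine, normalize_map

logger = logging.getLogger(__name__)

DEFAULT_START = 0.2
DEFAULT_BOUNDS = (0.0, 1.0)


@dataclass
class WeightVector:
    """Nonnegative constraint weights, each bounded to [0, 1]."""

    fc: float
    torque: float
    nga: float
    oga: float
    vis: float

    def __post_init__(self):
        for label, w in zip(PENALTY_LABELS, self.as_array()):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {label} = {w} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.fc, self.torque, self.nga, self.oga, self.vis])

    @classmethod
    def from_array(cls, w) -> "WeightVector":
        w = np.asarray(w, dtype=float)
        if w.shape != (5,):
            raise ValueError("expected 5 weights")
        return cls(*w)

    @classmethod
    def equal(cls, value: float = 1.0) -> "WeightVector":
        return cls(value, value, value, value, value)

    def relative(self) -> np.ndarray:
        return relative_weights(self)

    def to_dict(self) -> dict:
        return dict(zip(PENALTY_LABELS, (float(x) for x in self.as_array())))


def relative_weights(w: WeightVector | np.ndarray) -> np.ndarray:
    """Weights as fractions of their sum (sum to 1)."""
    arr = w.as_array() if isinstance(w, WeightVector) else np.asarray(w, float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("relative weights undefined for all-zero weights")
    return arr / total


@dataclass
class FitProblem:
    """Stacked data for one weight fit, flattened over unmasked pairs."""

    penalty_stack: np.ndarray  # (5, K) normalized penalties
    p_h: np.ndarray  # (K,) observed-grasp penalty: 0 selected, 1 otherwise
    r: np.ndarray  # (K,) regularization weights
    n_selected: int  # total observed grasps (with repetitions)
    n_nonselected: int  # unmasked pairs never selected
    selection_counts: dict = field(default_factory=dict)  # (ti, ii) -> count

    @property
    def n_pairs(self) -> int:
        return self.p_h.shape[0]


def build_fit_problem(maps, observed) -> FitProblem:
    """Assemble the fit target from normalized maps and snapped grasps.

    Selected pairs get target penalty 0 and regularization equal to
    their selection count; every other unmasked pair gets target 1 and
    regularization ``n_selected / n_nonselected``, so both regions sum
    to ``n_selected``.
    """
    maps = list(maps)
    if len(maps) != 5:
        raise ValueError("expected the five penalty maps")
    for m in maps:
        if not m.normalized:
            raise ValueError(f"map {m.label} must be normalized")
    observed = list(observed)
    if not observed:
        raise ValueError("no observed grasps")

    counts: Counter = Counter()
    for g in observed:
        if g.thumb_idx is None or g.index_idx is None:
            raise ValueError(
                "observed grasps must be snapped to candidates "
                "(see grasp_manifold.project_contacts)"
            )
        counts[(g.thumb_idx, g.index_idx)] += g.count

    mask = np.zeros_like(maps[0].mask)
    for m in maps:
        mask |= m.mask
    valid = ~mask
    n = maps[0].n

    sel = np.zeros((n, n))
    for (ti, ii), c in counts.items():
        if mask[ti, ii]:
            raise ValueError(f"observed grasp at masked pair ({ti}, {ii})")
        sel[ti, ii] = c

    n_selected = int(sum(counts.values()))
    n_nonselected = int(valid.sum()) - len(counts)
    if n_nonselected <= 0:
        raise ValueError("every pair was selected; nothing to contrast")

    p_h = np.where(sel > 0, 0.0, 1.0)
    r = np.where(sel > 0, sel, n_selected / n_nonselected)

    stack = np.stack([m.values[valid] for m in maps])
    return FitProblem(
        penalty_stack=stack,
        p_h=p_h[valid],
        r=r[valid],
        n_selected=n_selected,
        n_nonselected=n_nonselected,
        selection_counts=dict(counts),
    )


@dataclass
class FitResult:
    weights: WeightVector
    residual_norm: float  # 0.5 * sum of squared residuals at the solution
    start_residual_norm: float
    converged: bool
    status: int
    message: str
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.to_dict(),
            "relative_weights": dict(
                zip(PENALTY_LABELS, map(float, self.weights.relative()))
            ),
            "residual": self.residual_norm,
            "converged": self.converged,
            "solver_meta": {
                "status": self.status,
                "message": self.message,
                "n_iterations": self.n_iterations,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fit_weights(
    problem: FitProblem,
    start: float = DEFAULT_START,
    bounds: tuple = DEFAULT_BOUNDS,
    squared: bool = True,
    tol: float = 1e-8,
) -> FitResult:
    """Fit the five constraint weights by bounded trust-region least
    squares on the residual r * (sum_i w_i P_i^2 - p_h)."""
    stack = problem.penalty_stack**2 if squared else problem.penalty_stack

    def residual(w):
        return problem.r * (w @ stack - problem.p_h)

    x0 = np.full(5, start)
    lo, hi = bounds
    if not lo <= start <= hi:
        raise ValueError("start must lie within bounds")
    res = least_squares(
        residual, x0, bounds=(lo, hi), method="trf", xtol=tol, ftol=tol, gtol=tol
    )
    if res.status <= 0:
        logger.warning("weight fit did not converge: %s", res.message)
    start_cost = 0.5 * float(np.sum(residual(x0) ** 2))
    return FitResult(
        weights=WeightVector.from_array(np.clip(res.x, lo, hi)),
        residual_norm=float(res.cost),
        start_residual_norm=start_cost,
        converged=res.status > 0,
        status=int(res.status),
        message=str(res.message),
        n_iterations=int(res.nfev),
    )


def simulate_observer(
    maps,
    w_true: WeightVector,
    cands,
    n_trials: int,
    noise: float = 0.0,
    k_nearest: int = 5,
    seed=None,
    percentile: float = 0.1,
    squared: bool = True,
) -> list[Grasp]:
    """Generate synthetic observed grasps from known ground-truth weights.

    The weighted combined map is normalized and sampled with the same
    percentile-truncation / probability-weighted rule used for model
    predictions.  With ``noise`` > 0, each digit's candidate is replaced,
    with that probability, by one of its ``k_nearest`` spatial neighbours
    (candidate jitter).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    overall = normalize_map(combine(maps, w_true, squared=squared))
    grasps = sample_optimal_grasps(overall, cands, n_trials,
                                   percentile=percentile, seed=rng)
    if noise > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(cands.positions)
        k = min(k_nearest + 1, cands.n)
        _, nbrs = tree.query(cands.positions, k=k)
        jittered = []
        for g in grasps:
            ti, ii = g.thumb_idx, g.index_idx
            if rng.random() < noise:
                ti = int(rng.choice(nbrs[ti, 1:]))
            if rng.random() < noise:
                ii = int(rng.choice(nbrs[ii, 1:]))
            if ti == ii:  # keep the pair valid
                ti, ii = g.thumb_idx, g.index_idx
            jittered.append(
                Grasp(cands.positions[ti], cands.positions[ii],
                      thumb_idx=ti, index_idx=ii)
            )
        grasps = jittered
    return grasps
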