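"""Per-grasp penalty functions over the 2D (thumb, index) candidate space.

Each penalty is a square table indexed by ordered (thumb-candidate,
index-candidate) pairs.  Raw maps carry physical units (rad, N*m, mm, or
a fraction); per-object min-max normalization to [0, 1] makes them
commensurable before combination.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from graspsel.object_model import CandidateSet, RigidObject

logger = logging.getLogger(__name__)

#: Canonical order of the five penalty channels.
PENALTY_LABELS = ("FC", "T", "NGA", "OGA", "VIS")

#: Preferred grasp-axis direction (thumb -> index) in the participant
#: frame; unit-normalized on use.
DEFAULT_NGA_VECTOR = (0.49, 0.87, 0.0)

#: Aperture above which a linear penalty accrues (mm).
DEFAULT_APERTURE_THRESHOLD = 25.0

#: Default hand start location: 280 mm right, 95 mm forward, on the table.
DEFAULT_HAND_REFERENCE = (280.0, 95.0, 0.0)

GRAVITY = 9.81  # m/s^2, acting along -z


@dataclass
class ModelConfig:
    """Constraint parameters for the grasp-selection model."""

    nga_vector: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_NGA_VECTOR))
    aperture_threshold: float = DEFAULT_APERTURE_THRESHOLD
    gravity: float = GRAVITY
    hand_reference_point: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_HAND_REFERENCE)
    )
    table_z: float = 0.0
    squared_combination: bool = True  # weighted mode sums w_i * P_i**2

    def __post_init__(self):
        v = np.asarray(self.nga_vector, dtype=float).reshape(3)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("nga_vector must be nonzero")
        self.nga_vector = v / norm
        if self.aperture_threshold <= 0:
            raise ValueError("aperture_threshold must be positive")
        self.hand_reference_point = np.asarray(
            self.hand_reference_point, dtype=float
        ).reshape(3)

    def to_dict(self) -> dict:
        return {
            "nga_vector": [float(x) for x in self.nga_vector],
            "aperture_threshold": float(self.aperture_threshold),
            "gravity": float(self.gravity),
            "hand_reference_point": [float(x) for x in self.hand_reference_point],
            "table_z": float(self.table_z),
            "squared_combination": bool(self.squared_combination),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {k: d[k] for k in (
            "nga_vector", "aperture_threshold", "gravity",
            "hand_reference_point", "table_z", "squared_combination",
        ) if k in d}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PenaltyMap:
    """Square penalty table over ordered (thumb, index) candidate pairs."""

    values: np.ndarray  # (n, n)
    mask: np.ndarray  # (n, n) bool, True = invalid pair
    normalized: bool
    label: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("penalty map must be square")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def unmasked(self) -> np.ndarray:
        """Flat array of the valid entries."""
        return self.values[~self.mask]

    def copy(self) -> "PenaltyMap":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


def _diagonal_mask(n: int) -> np.ndarray:
    # thumb and index cannot share a triangle (zero-aperture pair)
    return np.eye(n, dtype=bool)


def _pair_angles(ref: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Angle between matched vectors via atan2(||cross||, dot); [0, pi]."""
    cross = np.cross(ref, vec)
    dot = np.einsum("...i,...i->...", ref, vec)
    return np.arctan2(np.linalg.norm(cross, axis=-1), dot)


def penalty_force_closure(cands: CandidateSet) -> PenaltyMap:
    """Sum of angular deviations of the grasp axis from both gripping
    force vectors (the inward surface normals); rad, range [0, 2*pi].
    """
    if cands.n < 2:
        raise ValueError("need at least 2 candidates")
    P = cands.positions
    F = -cands.normals  # gripping force direction at each candidate
    diff = P[None, :, :] - P[:, None, :]  # diff[i, j] = CP_j - CP_i
    # angle between thumb force F_i and axis (CP_j - CP_i); the index
    # term of pair (i, j) equals the thumb term of pair (j, i)
    a = _pair_angles(np.broadcast_to(F[:, None, :], diff.shape), diff)
    values = a + a.T
    return PenaltyMap(values, _diagonal_mask(cands.n), False, "FC")


def penalty_torque(
    cands: CandidateSet, obj: RigidObject, cfg: ModelConfig | None = None
) -> PenaltyMap:
    """Magnitude of the total gravitational torque about the contacts.

    Each digit is assumed to counteract the full object weight; lever
    arms in m, weight in N, so values are N*m.  Symmetric.
    """
    cfg = cfg or ModelConfig()
    weight = obj.mass / 1000.0 * cfg.gravity  # N
    counter_force = np.array([0.0, 0.0, weight])  # -F_g, upward
    lever = (obj.com[None, :] - cands.positions) / 1000.0  # m
    tau = np.cross(lever, counter_force)  # per-candidate torque
    total = tau[:, None, :] + tau[None, :, :]
    values = np.linalg.norm(total, axis=-1)
    return PenaltyMap(values, _diagonal_mask(cands.n), False, "T")


def penalty_nga(cands: CandidateSet, cfg: ModelConfig | None = None) -> PenaltyMap:
    """Angular deviation of the thumb->index axis from the natural grasp
    axis; rad, range [0, pi].  Asymmetric: P(i, j) + P(j, i) = pi.
    """
    cfg = cfg or ModelConfig()
    P = cands.positions
    diff = P[None, :, :] - P[:, None, :]
    values = _pair_angles(cfg.nga_vector, diff)
    return PenaltyMap(values, _diagonal_mask(cands.n), False, "NGA")


def penalty_aperture(cands: CandidateSet, cfg: ModelConfig | None = None) -> PenaltyMap:
    """Zero below the aperture threshold, then linear in the excess (mm)."""
    cfg = cfg or ModelConfig()
    P = cands.positions
    d = np.linalg.norm(P[None, :, :] - P[:, None, :], axis=-1)
    values = np.maximum(0.0, d - cfg.aperture_threshold)
    return PenaltyMap(values, _diagonal_mask(cands.n), False, "OGA")


def penalty_visibility(
    cands: CandidateSet, cfg: ModelConfig | None = None
) -> PenaltyMap:
    """Fraction of surface points occluded by the hand.

    Project candidates and contacts onto the horizontal plane; for each
    pair, the points strictly on the side of the 2D contact line that
    contains the projected hand reference point count as occluded.
    Range [0, 1].
    """
    cfg = cfg or ModelConfig()
    pts = cands.positions[:, :2]
    hand = cfg.hand_reference_point[:2]
    n = cands.n
    values = np.empty((n, n))
    degenerate_pairs = 0
    for i in range(n):
        a = pts[i]
        X = pts - a  # (n, 2) points relative to the thumb contact
        D = X.copy()  # line directions for each index candidate j
        # degenerate pairs (coincident projections, e.g. vertically
        # stacked candidates): line through the point perpendicular to
        # the hand direction
        deg = np.hypot(D[:, 0], D[:, 1]) < 1e-9
        if deg.any():
            degenerate_pairs += int(deg.sum()) - 1  # diagonal is masked anyway
            u = hand - a
            D[deg] = (-u[1], u[0])
        D /= np.hypot(D[:, 0], D[:, 1])[:, None]
        # signed point-line distance cross2(D_j, q) for all points q, as
        # one matmul; points within 1e-6 mm of the line count as on it
        Drot = np.column_stack([-D[:, 1], D[:, 0]])  # (n, 2)
        C = Drot @ X.T  # C[j, k] = cross2(D_j, X_k), mm
        ch = Drot @ (hand - a)  # side of the hand, per line
        side = np.where(ch >= 0, 1.0, -1.0)
        occluded = (C * side[:, None] > 1e-6).sum(axis=1)
        # hand on the line (edge-on): occlusion side undefined -> none
        occluded[np.abs(ch) <= 1e-6] = 0
        values[i] = occluded / n
    if degenerate_pairs:
        logger.info(
            "visibility: %d candidate pairs had coincident horizontal "
            "projections; used hand-perpendicular line", degenerate_pairs,
        )
    return PenaltyMap(values, _diagonal_mask(n), False, "VIS")


def normalize_map(m: PenaltyMap) -> PenaltyMap:
    """Min-max rescale the unmasked entries to [0, 1].

    A constant map carries no information and normalizes to all zeros.
    Idempotent on already-normalized maps.
    """
    vals = m.unmasked()
    if vals.size == 0:
        raise ValueError("cannot normalize a fully masked map")
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(m.values)
    if hi > lo:
        out[~m.mask] = (vals - lo) / (hi - lo)
    return PenaltyMap(out, m.mask.copy(), True, m.label)


def combine(maps, weights=None, squared: bool = True) -> PenaltyMap:
    """Combine five normalized penalty maps into the overall penalty.

    Unweighted mode (``weights`` is None): plain sum of the five maps,
    rescaled back to [0, 1].  Weighted mode: sum of w_i * P_i**2 (or
    w_i * P_i when ``squared`` is False), returned raw (not re-scaled).
    """
    maps = list(maps)
    if len(maps) != len(PENALTY_LABELS):
        raise ValueError(f"expected {len(PENALTY_LABELS)} maps, got {len(maps)}")
    n = maps[0].n
    for m in maps:
        if m.n != n:
            raise ValueError("penalty maps built on different candidate sets")
        if not m.normalized:
            raise ValueError(f"map {m.label} is not normalized")
    mask = np.zeros((n, n), dtype=bool)
    for m in maps:
        mask |= m.mask

    if weights is None:
        total = np.sum([m.values for m in maps], axis=0)
        out = PenaltyMap(total, mask, False, "OVERALL")
        return normalize_map(out)

    w = np.asarray(getattr(weights, "as_array", lambda: weights)(), dtype=float)
    if w.shape != (len(maps),):
        raise ValueError("need one weight per map")
    stack = np.stack([m.values for m in maps])
    if squared:
        stack = stack**2
    total = np.einsum("i,ijk->jk", w, stack)
    return PenaltyMap(total, mask, False, "OVERALL")


def compute_penalty_maps(
    cands: CandidateSet,
    obj: RigidObject,
    cfg: ModelConfig | None = None,
    normalized: bool = True,
) -> list[PenaltyMap]:
    """All five penalty maps in canonical order (FC, T, NGA, OGA, VIS)."""
    cfg = cfg or ModelConfig()
    maps = [
        penalty_force_closure(cands),
        penalty_torque(cands, obj, cfg),
        penalty_nga(cands, cfg),
        penalty_aperture(cands, cfg),
        penalty_visibility(cands, cfg),
    ]
    if normalized:
        maps = [normalize_map(m) for m in maps]
    return maps


# ---------------------------------------------------------------------------
# Map I/O
# ---------------------------------------------------------------------------


def save_map(m: PenaltyMap, path) -> None:
    """Write a penalty map as TSV plus a JSON sidecar (``<path>.json``)."""
    path = Path(path)
    np.savetxt(path, m.values, delimiter="\t", fmt="%.10g")
    sidecar = {
        "label": m.label,
        "n_candidates": int(m.n),
        "normalized": bool(m.normalized),
        "mask": "diagonal" if np.array_equal(m.mask, _diagonal_mask(m.n))
        else [[int(r), int(c)] for r, c in zip(*np.nonzero(m.mask))],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def load_map(path) -> PenaltyMap:
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n = meta["n_candidates"]
    if meta["mask"] == "diagonal":
        mask = _diagonal_mask(n)
    else:
        mask = np.zeros((n, n), dtype=bool)
        for r, c in meta["mask"]:
            mask[r, c] = True
    return PenaltyMap(values, mask, meta["normalized"], meta["label"])
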