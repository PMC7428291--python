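"""The 2D ordered grasp space: sampling optima and snapping observations."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from graspsel.object_model import CandidateSet, RigidObject
from graspsel.penalty_maps import PenaltyMap

logger = logging.getLogger(__name__)

#: Snap distances above this flag a contact record as suspect (mm).
SNAP_SUSPECT_MM = 20.0


@dataclass
class Grasp:
    """A two-digit grasp: thumb and index contact positions (mm)."""

    thumb: np.ndarray
    index: np.ndarray
    thumb_idx: int | None = None  # candidate indices, if snapped/sampled
    index_idx: int | None = None
    count: int = 1
    suspect: bool = False

    def __post_init__(self):
        self.thumb = np.asarray(self.thumb, dtype=float).reshape(3)
        self.index = np.asarray(self.index, dtype=float).reshape(3)

    @property
    def vector(self) -> np.ndarray:
        """6D grasp vector [xT, yT, zT, xI, yI, zI]."""
        return np.concatenate([self.thumb, self.index])

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.thumb + self.index)

    @property
    def aperture(self) -> float:
        return float(np.linalg.norm(self.index - self.thumb))

    def transformed(self, transform) -> "Grasp":
        return Grasp(
            transform.apply(self.thumb), transform.apply(self.index),
            self.thumb_idx, self.index_idx, self.count, self.suspect,
        )


def grasp_vectors(grasps) -> np.ndarray:
    """Stack grasps into an (n, 6) array."""
    return np.array([g.vector for g in grasps], dtype=float).reshape(-1, 6)


def manifold_coordinates(cands: CandidateSet) -> np.ndarray:
    """Deterministic candidate ordering shared by the thumb (row) and
    index (column) axes of every penalty map: mesh face order."""
    return np.arange(cands.n, dtype=np.int64)


def pair_to_rc(thumb_idx: int, index_idx: int) -> tuple[int, int]:
    """Map an ordered (thumb, index) candidate pair to (row, col)."""
    return thumb_idx, index_idx


def rc_to_pair(row: int, col: int) -> tuple[int, int]:
    return row, col


def sample_optimal_grasps(
    overall: PenaltyMap,
    cands: CandidateSet,
    n: int,
    percentile: float = 0.1,
    seed=None,
) -> list[Grasp]:
    """Sample predicted optimal grasps from the overall penalty map.

    Pairs with penalty above the lower ``percentile``-th percentile are
    discarded; the survivors are drawn with replacement with probability
    proportional to (1 - penalty).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not overall.normalized:
        raise ValueError("overall map must be normalized before sampling")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    valid = ~overall.mask
    vals = overall.values[valid]
    pct = percentile
    rows, cols = np.nonzero(valid)
    while True:
        cutoff = np.percentile(vals, pct)
        keep = vals <= cutoff
        if keep.any():
            break
        warnings.warn(
            f"no grasps at or below the {pct}th percentile; widening",
            stacklevel=2,
        )
        pct = min(pct * 10, 100.0)
    sr, sc, sv = rows[keep], cols[keep], vals[keep]

    weights = np.clip(1.0 - sv, 0.0, None)
    total = weights.sum()
    p = weights / total if total > 0 else np.full(len(sv), 1.0 / len(sv))
    picks = rng.choice(len(sv), size=n, replace=True, p=p)
    return [
        Grasp(cands.positions[sr[k]], cands.positions[sc[k]],
              thumb_idx=int(sr[k]), index_idx=int(sc[k]))
        for k in picks
    ]


def project_contacts(
    obj: RigidObject,
    cands: CandidateSet,
    thumb_xyz,
    index_xyz,
    suspect_mm: float = SNAP_SUSPECT_MM,
) -> Grasp:
    """Snap measured fingertip positions to the nearest accessible
    candidate contact points (Euclidean, participant frame).

    Records with a snap distance above ``suspect_mm`` are flagged as
    suspect (likely tracking error) but still returned.
    """
    pts = np.vstack([np.asarray(thumb_xyz, float), np.asarray(index_xyz, float)])
    d = cdist(pts, cands.positions)
    ti, ii = int(d[0].argmin()), int(d[1].argmin())
    snap = (float(d[0, ti]), float(d[1, ii]))
    suspect = max(snap) > suspect_mm
    if suspect:
        logger.warning(
            "contact snapped %.1f/%.1f mm (> %.0f mm): flagged suspect",
            snap[0], snap[1], suspect_mm,
        )
    else:
        logger.debug("contact snap distances: %.2f / %.2f mm", *snap)
    return Grasp(
        cands.positions[ti], cands.positions[ii],
        thumb_idx=ti, index_idx=ii, suspect=suspect,
    )


# ---------------------------------------------------------------------------
# Grasp table text I/O
# ---------------------------------------------------------------------------

GRASP_COLUMNS = ["trial_id", "xT", "yT", "zT", "xI", "yI", "zI"]


def grasps_to_frame(grasps, **extra_columns) -> pd.DataFrame:
    """Tabulate grasps in the standard delimited-text schema (mm)."""
    v = grasp_vectors(grasps)
    df = pd.DataFrame(v, columns=GRASP_COLUMNS[1:])
    df.insert(0, "trial_id", np.arange(len(df)))
    for name, val in extra_columns.items():
        df[name] = val
    return df


def frame_to_grasps(df: pd.DataFrame) -> list[Grasp]:
    missing = [c for c in GRASP_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"grasp table missing columns: {missing}")
    return [
        Grasp(row[["xT", "yT", "zT"]].to_numpy(float),
              row[["xI", "yI", "zI"]].to_numpy(float))
        for _, row in df.iterrows()
    ]


def write_grasps(path, grasps, **extra_columns) -> None:
    grasps_to_frame(grasps, **extra_columns).to_csv(path, sep="\t", index=False)


def read_grasps(path) -> list[Grasp]:
    return frame_to_grasps(pd.read_csv(path, sep="\t"))
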