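"""Landmark-based registration: rigid initialization, thin-plate splines, TRE.

The 3D micro-ultrasound-to-MRI step is a rigid initialization (standing in
for manual visual alignment) followed by a landmark thin-plate-spline warp.
Accuracy is quantified as the target registration error (TRE) on evaluation
landmarks that are disjoint from the control landmarks, with an optional
single-pass 2-standard-deviation outlier exclusion and quadrature combination
of per-step errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

SIDE_CONDITION_TOL = 1e-8


@dataclass(frozen=True)
class Landmark:
    """A named point used either to fit the warp (control) or to score it (evaluation)."""

    name: str
    position: np.ndarray
    role: str = "control"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"landmark {self.name!r} has non-finite position")
        object.__setattr__(self, "position", pos)
        if self.role not in ("control", "evaluation"):
            raise ValueError("role must be 'control' or 'evaluation'")


def landmark_array(landmarks: list[Landmark]) -> np.ndarray:
    return np.array([lm.position for lm in landmarks], dtype=float)


# ---------------------------------------------------------------------------
# transforms


@dataclass(frozen=True)
class RigidTransform:
    """p -> R @ p + t (no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape[0] != R.shape[1] or R.shape[0] != t.shape[0]:
            raise ValueError("inconsistent rotation/translation shapes")
        if not np.allclose(R @ R.T, np.eye(R.shape[0]), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def dimension(self) -> int:
        return self.rotation.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.rotation.T + self.translation

    @classmethod
    def identity(cls, dimension: int) -> "RigidTransform":
        return cls(np.eye(dimension), np.zeros(dimension))


def _tps_kernel(r: np.ndarray, dimension: int) -> np.ndarray:
    """Polyharmonic kernel: U(r) = r^2 log r in 2D, U(r) = r in 3D."""
    if dimension == 2:
        out = np.zeros_like(r)
        pos = r > 0
        out[pos] = r[pos] ** 2 * np.log(r[pos])
        return out
    return r


@dataclass(frozen=True)
class ThinPlateSplineTransform:
    """Affine part plus radial kernel terms anchored at the control points."""

    dimension: int
    control_points: np.ndarray  # (n, d) source positions
    affine: np.ndarray          # (d+1, d): row 0 translation, rows 1..d linear
    weights: np.ndarray         # (n, d) kernel coefficients
    regularization: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.control_points, dtype=float)
        a = np.asarray(self.affine, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        d = self.dimension
        if d not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if c.shape[1] != d or a.shape != (d + 1, d) or w.shape != c.shape:
            raise ValueError("inconsistent TPS coefficient shapes")
        object.__setattr__(self, "control_points", c)
        object.__setattr__(self, "affine", a)
        object.__setattr__(self, "weights", w)
        # side conditions: kernel weights carry no affine component
        if c.shape[0]:
            if np.abs(w.sum(axis=0)).max() > SIDE_CONDITION_TOL * max(1, len(c)):
                raise ValueError("TPS side condition violated: sum of weights != 0")
            if np.abs(c.T @ w).max() > SIDE_CONDITION_TOL * max(1.0, np.abs(c).max()) * len(c):
                raise ValueError("TPS side condition violated: first moment != 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if p.shape[1] != self.dimension:
            raise ValueError(
                f"points are {p.shape[1]}D but transform is {self.dimension}D"
            )
        out = self.affine[0] + p @ self.affine[1:]
        if len(self.control_points):
            K = _tps_kernel(cdist(p, self.control_points), self.dimension)
            out = out + K @ self.weights
        return out

    def to_dict(self) -> dict:
        return {
            "type": "tps",
            "dimension": self.dimension,
            "control_points": self.control_points.tolist(),
            "affine": self.affine.tolist(),
            "weights": self.weights.tolist(),
            "regularization": self.regularization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThinPlateSplineTransform":
        return cls(
            dimension=int(d["dimension"]),
            control_points=np.asarray(d["control_points"], dtype=float),
            affine=np.asarray(d["affine"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            regularization=float(d.get("regularization", 0.0)),
        )


@dataclass(frozen=True)
class CompositeTransform:
    """Transforms applied in listed order: steps[0] first."""

    steps: tuple

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(points, dtype=float))
        for step in self.steps:
            out = step.apply(out)
        return out


def apply_transform(transform, points: np.ndarray) -> np.ndarray:
    """Apply a transform (or an ordered chain given as list/tuple) to points."""
    if isinstance(transform, (list, tuple)):
        transform = CompositeTransform(tuple(transform))
    return transform.apply(points)


# ---------------------------------------------------------------------------
# fitting


def initialize_alignment(
    moving_points: np.ndarray, fixed_points: np.ndarray
) -> RigidTransform:
    """Rigid initialization aligning centroids and principal axes (no scaling).

    Stands in for manual visual alignment. The principal-axis sign ambiguity
    is resolved by picking the proper rotation minimizing the summed distance
    between the transformed moving set and the fixed set (paired when counts
    match, nearest-neighbor otherwise).
    """
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    fix = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    d = mov.shape[1]
    if fix.shape[1] != d:
        raise ValueError("point sets must share dimension")
    if len(mov) < 3 or len(fix) < 3:
        raise ValueError("need at least 3 points per set")

    cm, cf = mov.mean(axis=0), fix.mean(axis=0)
    Um = np.linalg.svd((mov - cm).T @ (mov - cm))[0]
    Uf = np.linalg.svd((fix - cf).T @ (fix - cf))[0]
    if np.linalg.svd((mov - cm), compute_uv=False)[-1] < 1e-9 * max(
        1.0, np.abs(mov).max()
    ):
        raise ValueError("moving points are degenerate (collinear/coplanar)")

    tree = cKDTree(fix)
    best = None
    for signs in np.ndindex(*(2,) * d):
        D = np.diag([1.0 if s == 0 else -1.0 for s in signs])
        R = Uf @ D @ Um.T
        if np.linalg.det(R) < 0:
            continue
        moved = (mov - cm) @ R.T + cf
        if len(mov) == len(fix):
            cost = np.linalg.norm(moved - fix, axis=1).sum()
        else:
            cost = tree.query(moved)[0].sum()
        if best is None or cost < best[0]:
            best = (cost, R)
    _, R = best
    return RigidTransform(rotation=R, translation=cf - R @ cm)


def fit_tps(
    source: np.ndarray | list[Landmark],
    target: np.ndarray | list[Landmark],
    dimension: int | None = None,
    regularization: float = 0.0,
) -> ThinPlateSplineTransform:
    """Fit a thin-plate spline mapping source control points to targets.

    With ``regularization == 0`` the warp interpolates the control points
    exactly; the standard side conditions (zero sum and zero first moment of
    the kernel weights) are enforced by the linear system.
    """
    src = source if isinstance(source, np.ndarray) else landmark_array(source)
    tgt = target if isinstance(target, np.ndarray) else landmark_array(target)
    src = np.atleast_2d(np.asarray(src, dtype=float))
    tgt = np.atleast_2d(np.asarray(tgt, dtype=float))
    if src.shape != tgt.shape:
        raise ValueError("source and target must have matching shapes")
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    n, d = src.shape
    if dimension is None:
        dimension = d
    if dimension != d:
        raise ValueError("dimension does not match point dimension")
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} control points in {d}D")

    dists = cdist(src, src)
    iu = np.triu_indices(n, k=1)
    if dists[iu].min() < 1e-9:
        i, j = iu[0][np.argmin(dists[iu])], iu[1][np.argmin(dists[iu])]
        raise ValueError(f"coincident control points at indices {i} and {j}")

    K = _tps_kernel(dists, d) + regularization * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + d + 1, n + d + 1))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + d + 1, d))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate control-point configuration") from exc
    weights, affine = sol[:n], sol[n:]
    # kill solver round-off so side conditions hold to tight tolerance
    weights = weights - P @ np.linalg.lstsq(P, weights, rcond=None)[0]
    return ThinPlateSplineTransform(
        dimension=d,
        control_points=src,
        affine=affine,
        weights=weights,
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# TRE evaluation


@dataclass
class TREReport:
    """Per-pair target registration errors with mean ± standard error."""

    per_pair_mm: np.ndarray
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_pair_mm = np.asarray(self.per_pair_mm, dtype=float)
        if np.any(self.per_pair_mm < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def kept_mm(self) -> np.ndarray:
        mask = np.ones(len(self.per_pair_mm), dtype=bool)
        mask[self.excluded] = False
        return self.per_pair_mm[mask]

    @property
    def mean_mm(self) -> float:
        return float(self.kept_mm.mean())

    @property
    def se_mm(self) -> float:
        kept = self.kept_mm
        if len(kept) < 2:
            return 0.0
        return float(kept.std(ddof=1) / np.sqrt(len(kept)))

    @property
    def excluded_percent(self) -> float:
        """Percentage of landmarks removed by the outlier rule."""
        return 100.0 * len(self.excluded) / len(self.per_pair_mm)

    def to_dict(self) -> dict:
        return {
            "per_pair_mm": self.per_pair_mm.tolist(),
            "excluded": list(self.excluded),
            "mean_mm": self.mean_mm,
            "se_mm": self.se_mm,
            "n_total": int(len(self.per_pair_mm)),
            "n_excluded": int(len(self.excluded)),
            "excluded_percent": self.excluded_percent,
        }


def compute_tre(
    moving_points: np.ndarray, fixed_points: np.ndarray, transform=None
) -> TREReport:
    """Euclidean distances between transformed moving and fixed evaluation points.

    Evaluation points must be disjoint from control points: controls would
    trivially report zero error under exact interpolation.
    """
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    fix = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    if mov.size == 0:
        raise ValueError("no evaluation pairs given")
    if mov.shape != fix.shape:
        raise ValueError("moving/fixed evaluation sets must match in shape")
    moved = apply_transform(transform, mov) if transform is not None else mov
    return TREReport(per_pair_mm=np.linalg.norm(moved - fix, axis=1))


def exclude_tre_outliers(
    distances: np.ndarray, k: float = 2.0
) -> tuple[np.ndarray, list[int]]:
    """Single-pass removal of distances greater than mean + k * sd.

    Mean and standard deviation are computed once over all inputs; the
    exclusion is not iterated.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 3:
        warnings.warn("fewer than 3 distances: no outlier exclusion", stacklevel=2)
        return d, []
    threshold = d.mean() + k * d.std(ddof=1)
    excluded = [int(i) for i in np.nonzero(d > threshold)[0]]
    kept = np.delete(d, excluded)
    return kept, excluded


def combine_quadrature(
    step_means: np.ndarray, step_ses: np.ndarray
) -> tuple[float, float]:
    """Combine independent per-step errors as sqrt of the sum of squares."""
    m = np.asarray(step_means, dtype=float)
    s = np.asarray(step_ses, dtype=float)
    if m.shape != s.shape:
        raise ValueError("means and standard errors must have equal length")
    if np.any(m < 0) or np.any(s < 0):
        raise ValueError("quadrature inputs must be nonnegative")
    return float(np.sqrt(np.sum(m**2))), float(np.sqrt(np.sum(s**2)))


# ---------------------------------------------------------------------------
# serialization


def save_transform(transform, path) -> None:
    """Serialize a TPS / rigid / composite transform chain to JSON."""

    def encode(t) -> dict:
        if isinstance(t, ThinPlateSplineTransform):
            return t.to_dict()
        if isinstance(t, RigidTransform):
            return {
                "type": "rigid",
                "rotation": t.rotation.tolist(),
                "translation": t.translation.tolist(),
            }
        if isinstance(t, CompositeTransform):
            return {"type": "composite", "steps": [encode(s) for s in t.steps]}
        raise TypeError(f"cannot serialize transform of type {type(t).__name__}")

    with open(path, "w") as fh:
        json.dump(encode(transform), fh, indent=2)


def load_transform(path):
    with open(path) as fh:
        d = json.load(fh)

    def decode(d: dict):
        if d["type"] == "tps":
            return ThinPlateSplineTransform.from_dict(d)
        if d["type"] == "rigid":
            return RigidTransform(
                rotation=np.asarray(d["rotation"], dtype=float),
                translation=np.asarray(d["translation"], dtype=float),
            )
        if d["type"] == "composite":
            return CompositeTransform(tuple(decode(s) for s in d["steps"]))
        raise ValueError(f"unknown transform type {d['type']!r}")

    return decode(d)
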