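"""Least-squares rigid transformation between corresponding COP clouds.

The RIGID method treats the insole-frame COP and the shoe-frame COP (the
inverse-pose image of the platform COP) at synchronized, ground-contact
frames as corresponding clusters of points in two planar reference frames,
and solves

    min_{theta, d}  sum_i || R(theta) p_i + d - q_i ||^2

by singular value decomposition of the centered cross-covariance (the
Kabsch/Procrustes solution), with the determinant sign corrected so the
result is a proper rotation.  Both clouds are planar, so the fit is
restricted to rotations about the insole Z axis and in-plane translations —
the identifiable subspace; on planar data this coincides with the general
3-D solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .errors import DegenerateGeometryError, InsufficientDataError
from .frames import PlanarCOPSeries

MIN_PAIRS = 3


@dataclass
class RigidTransform:
    """Planar rotation about Z plus in-plane translation (insole -> shoe)."""

    theta_rad: float
    d_mm: np.ndarray            # (2,)

    def __post_init__(self):
        self.d_mm = np.asarray(self.d_mm, dtype=float).reshape(2)

    @property
    def rotation2(self) -> np.ndarray:
        c, s = np.cos(self.theta_rad), np.sin(self.theta_rad)
        return np.array([[c, -s], [s, c]])

    @property
    def rotation3(self) -> np.ndarray:
        r = np.eye(3)
        r[:2, :2] = self.rotation2
        return r

    @property
    def matrix4(self) -> np.ndarray:
        t = np.eye(4)
        t[:3, :3] = self.rotation3
        t[:2, 3] = self.d_mm
        return t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(-self.theta_rad, -self.rotation2.T @ self.d_mm)

    def objective(self, source: np.ndarray, target: np.ndarray) -> float:
        """Sum of squared residuals (mm^2) over corresponding points."""
        res = source @ self.rotation2.T + self.d_mm - target
        return float(np.sum(res**2))


def _paired_points(source: PlanarCOPSeries, target: PlanarCOPSeries):
    if len(source) != len(target):
        raise InsufficientDataError("source and target series lengths disagree")
    both = source.valid & target.valid
    return source.xy[both], target.xy[both]


def fit_rigid(source: PlanarCOPSeries, target: PlanarCOPSeries) -> RigidTransform:
    """Fit the insole->shoe rigid transform from corresponding COP frames.

    Only jointly valid (contact-gated) frames enter the correspondence set;
    frames are weighted equally.  Raises :class:`InsufficientDataError` for
    fewer than three pairs and :class:`DegenerateGeometryError` when the
    source cloud has no spread.
    """
    p, q = _paired_points(source, target)
    if len(p) < MIN_PAIRS:
        raise InsufficientDataError(
            f"need at least {MIN_PAIRS} jointly valid frames, have {len(p)}")
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    spread = np.sqrt(np.mean(np.sum(p0**2, axis=1)))
    if spread < 1e-9:
        raise DegenerateGeometryError("source COP cloud has zero spread")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    # Kabsch sign correction: exclude reflections
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, sign]) @ u.T
    theta = float(np.arctan2(r[1, 0], r[0, 0]))
    d = q.mean(axis=0) - r @ p.mean(axis=0)
    return RigidTransform(theta_rad=theta, d_mm=d)


def apply_rigid(t: RigidTransform, cop: PlanarCOPSeries) -> PlanarCOPSeries:
    """Map an insole-frame COP series into the shoe frame; mask preserved."""
    xy = cop.xy @ t.rotation2.T + t.d_mm
    return PlanarCOPSeries(xy=xy, valid=cop.valid.copy(), frame="shoe")


# --- serialization ----------------------------------------------------------

def transform_to_text(t: RigidTransform) -> str:
    return yaml.safe_dump({
        "theta_deg": float(np.degrees(t.theta_rad)),
        "d_mm": [float(v) for v in t.d_mm],
        "matrix4": [[float(v) for v in row] for row in t.matrix4],
    }, sort_keys=False)


def transform_from_text(text: str) -> RigidTransform:
    doc = yaml.safe_load(text)
    return RigidTransform(theta_rad=float(np.radians(doc["theta_deg"])),
                          d_mm=np.asarray(doc["d_mm"], dtype=float))


def write_transform(path, t: RigidTransform) -> None:
    with open(path, "w") as fh:
        fh.write(transform_to_text(t))


def read_transform(path) -> RigidTransform:
    with open(path) as fh:
        return transform_from_text(fh.read())
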