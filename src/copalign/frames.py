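"""Shoe coordinate frames and center-of-pressure series.

The shoe frame is built per time frame from three markers: the Y axis points
from the heel toward the midpoint of the 1st/5th metatarsal-head markers
(anterio-posterior, AP), the Z axis is the normal of the marker plane
(upward), and X = Y x Z (medio-lateral, ML).  The origin is the heel marker
with its Z coordinate set to zero, because COP is planar data on the walking
surface.

COP is planar by construction everywhere in this package: force-platform COP
lives on the plate surface, insole COP in the insole plane, and shoe-frame
COP is the inverse-pose image of the global COP projected onto the shoe XY
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateGeometryError
from .signal_io import (ForcePlateRecording, InsoleRecording, MarkerTrajectory,
                        SensorGeometry)

_COLLINEAR_TOL = 1e-8


@dataclass
class ShoeFramePose:
    """Per-frame homogeneous transforms from shoe to global coordinates."""

    matrices: np.ndarray        # (n, 4, 4)
    valid: np.ndarray           # (n,) bool

    def __len__(self):
        return len(self.matrices)


@dataclass
class PlanarCOPSeries:
    """Per-frame XY COP (mm) in a named frame; Z is implicitly zero."""

    xy: np.ndarray              # (n, 2)
    valid: np.ndarray           # (n,) bool
    frame: str = "global"       # global | shoe | insole

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise DataError(f"COP series must be (n, 2), got {self.xy.shape}")
        if len(self.xy) != len(self.valid):
            raise DataError("COP series and mask lengths disagree")

    def __len__(self):
        return len(self.xy)


def shoe_frame(heel, mt1, mt5) -> np.ndarray:
    """One 4x4 shoe-to-global transform from three marker positions (mm).

    Raises :class:`DegenerateGeometryError` for collinear or coincident
    markers.  The rotation is orthonormal and right-handed by construction.
    """
    heel = np.asarray(heel, dtype=float)
    mt1 = np.asarray(mt1, dtype=float)
    mt5 = np.asarray(mt5, dtype=float)
    mid = 0.5 * (mt1 + mt5)
    y = mid - heel
    ny = np.linalg.norm(y)
    z = np.cross(mt5 - heel, mt1 - heel)
    nz = np.linalg.norm(z)
    scale = max(np.linalg.norm(mt1 - heel), np.linalg.norm(mt5 - heel), 1.0)
    if ny < _COLLINEAR_TOL * scale or nz < _COLLINEAR_TOL * scale**2:
        raise DegenerateGeometryError("markers are collinear or coincident")
    y = y / ny
    z = z / nz
    x = np.cross(y, z)
    t = np.eye(4)
    t[:3, 0] = x
    t[:3, 1] = y
    t[:3, 2] = z
    t[:3, 3] = [heel[0], heel[1], 0.0]   # heel with Z zeroed: COP is planar
    return t


def shoe_frame_series(markers: MarkerTrajectory) -> ShoeFramePose:
    """Per-frame poses; frames with occluded or degenerate markers flagged."""
    n = len(markers)
    mats = np.tile(np.eye(4), (n, 1, 1))
    valid = markers.valid.copy()
    for i in range(n):
        if not valid[i]:
            continue
        try:
            mats[i] = shoe_frame(markers.heel[i], markers.mt1[i], markers.mt5[i])
        except DegenerateGeometryError:
            valid[i] = False
    return ShoeFramePose(matrices=mats, valid=valid)


def forceplate_cop(plate: ForcePlateRecording, contact: np.ndarray) -> PlanarCOPSeries:
    """COP on the walking surface by moment balance, in global mm.

    With moments taken about the plate origin o and the COP constrained to
    the surface plane z = z_s:

        x = o_x + ((z_s - o_z) Fx - My) / Fz
        y = o_y + ((z_s - o_z) Fy + Mx) / Fz

    Off-ground frames (``contact`` false) are masked, not computed.
    """
    contact = np.asarray(contact, dtype=bool)
    if len(contact) != len(plate):
        raise DataError("contact mask length disagrees with plate record")
    fz = plate.fz
    safe = contact & (np.abs(fz) > 1e-12)
    fzs = np.where(safe, fz, 1.0)
    dz = plate.surface_z_mm - plate.origin_mm[2]
    x = plate.origin_mm[0] + (dz * plate.force_n[:, 0] - plate.moment_nmm[:, 1]) / fzs
    y = plate.origin_mm[1] + (dz * plate.force_n[:, 1] + plate.moment_nmm[:, 0]) / fzs
    xy = np.column_stack([x, y])
    xy[~safe] = np.nan
    return PlanarCOPSeries(xy=xy, valid=safe, frame="global")


def insole_cop(rec: InsoleRecording, geom: SensorGeometry) -> PlanarCOPSeries:
    """Force-weighted centroid of sensor centers, in the insole frame.

    Weights are pressure x sensor area; frames with zero total force are
    masked (centroid undefined), never an error.
    """
    weights = rec.pressure_kpa * geom.areas_mm2   # (n, 99), ∝ N
    total = weights.sum(axis=1)
    valid = total > 0
    tot = np.where(valid, total, 1.0)
    xy = (weights @ geom.centers_mm) / tot[:, None]
    xy[~valid] = np.nan
    return PlanarCOPSeries(xy=xy, valid=valid, frame="insole")


def to_shoe_frame(pose: ShoeFramePose, cop_global: PlanarCOPSeries) -> PlanarCOPSeries:
    """Express a global planar COP series in the shoe frame.

    Applies the inverse pose per frame and drops Z (the mapping targets and
    all error reporting are 2-D: AP = shoe Y, ML = shoe X).
    """
    if len(pose) != len(cop_global):
        raise DataError("pose and COP series lengths disagree")
    valid = pose.valid & cop_global.valid
    xy = np.full((len(pose), 2), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size:
        mats = pose.matrices[idx]
        rot = mats[:, :3, :3]
        trans = mats[:, :3, 3]
        pts = np.zeros((idx.size, 3))
        pts[:, :2] = cop_global.xy[idx]
        # inverse of a rigid transform: R^T (p - t)
        local = np.einsum("nji,nj->ni", rot, pts - trans)
        xy[idx] = local[:, :2]
    return PlanarCOPSeries(xy=xy, valid=valid, frame="shoe")


def apply_pose(pose: ShoeFramePose, cop_shoe: PlanarCOPSeries) -> PlanarCOPSeries:
    """Inverse of :func:`to_shoe_frame`: shoe-frame planar points to global XY."""
    if len(pose) != len(cop_shoe):
        raise DataError("pose and COP series lengths disagree")
    valid = pose.valid & cop_shoe.valid
    xy = np.full((len(pose), 2), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size:
        mats = pose.matrices[idx]
        pts = np.zeros((idx.size, 3))
        pts[:, :2] = cop_shoe.xy[idx]
        world = np.einsum("nij,nj->ni", mats[:, :3, :3], pts) + mats[:, :3, 3]
        xy[idx] = world[:, :2]
    return PlanarCOPSeries(xy=xy, valid=valid, frame="global")


def write_cop(path, cop: PlanarCOPSeries) -> None:
    import pandas as pd
    tab = pd.DataFrame({"frame": np.arange(len(cop)), "x": cop.xy[:, 0],
                        "y": cop.xy[:, 1], "valid": cop.valid.astype(int)})
    with open(path, "w") as fh:
        fh.write(f"# frame = {cop.frame}\n")
        tab.to_csv(fh, index=False, float_format="%.6f")
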